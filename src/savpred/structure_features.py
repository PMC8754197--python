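"""Native structure-derived features and ingestion of tool-derived ones.

Solvent accessible surface area (SASA) is computed with the Shrake-Rupley
algorithm: quasi-uniform test points (a golden-spiral lattice) are placed on
each atom's probe-inflated sphere and the accessible fraction is the share
of points not buried inside any neighbour's inflated sphere.  Defaults: a
1.4 A water probe and 960 points per atom.

The remaining structure features either come from simple rules (active-site
probability binarized at a strict 0.5 threshold; unfolded-state reference
energies looked up in a 20-entry table) or are ingested from a TSV of
precomputed third-party predictions (folding free-energy change, PSIC
profile scores, epistatic energy change, functional impact score,
knowledge-based mutant potential, active-site probability).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .anm_dynamics import StructureModel

__all__ = [
    "VDW_RADII",
    "SasaProfile",
    "ExternalFeatureRecord",
    "ReferenceEnergyTable",
    "shrake_rupley_sasa",
    "binarize_active_site",
    "reference_energy_features",
    "ingest_external_features",
    "sasa_to_tsv",
]

logger = logging.getLogger(__name__)

# van der Waals radii (A) by element for heavy-atom structures
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: radius used when a structure is a bare Calpha trace (one pseudo-atom per
#: residue); coarse beads need a larger sphere than a lone carbon
CA_ONLY_RADIUS = 1.9


@dataclass(frozen=True)
class SasaProfile:
    """Per-residue solvent accessible surface area in A^2."""

    values: np.ndarray
    probe: float
    n_points: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("negative SASA values")


def golden_spiral(n_points: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit-sphere points on a golden-angle spiral."""
    i = np.arange(n_points) + 0.5
    z = 1.0 - 2.0 * i / n_points
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _atom_radii(model: StructureModel, radii: Mapping[str, float],
                ca_only_radius: float) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten atoms to (coords, radii); Calpha-only traces get the coarse radius."""
    ca_only = all(
        len(res.atoms) == 1 and res.atoms[0].name == "CA"
        for res in model.residues
    )
    coords, rads, owners = [], [], []
    for k, res in enumerate(model.residues):
        atoms = res.atoms or ()
        if not atoms:
            raise ValueError(
                f"residue {res.number} has no atom records for SASA"
            )
        for atom in atoms:
            if ca_only:
                r = ca_only_radius
            else:
                if atom.element not in radii:
                    raise ValueError(
                        f"no radius for atom {atom.name!r} (element "
                        f"{atom.element!r}) in residue {res.number}"
                    )
                r = radii[atom.element]
            coords.append(atom.coord)
            rads.append(r)
            owners.append(k)
    return (
        np.asarray(coords, dtype=float),
        np.asarray(rads, dtype=float),
        np.asarray(owners, dtype=int),
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Optional[Mapping[str, float]] = None,
    ca_only_radius: float = CA_ONLY_RADIUS,
) -> SasaProfile:
    """Shrake-Rupley SASA with golden-spiral quadrature.

    Per atom: test points on the sphere of radius ``r_atom + probe`` that lie
    strictly inside no neighbour's inflated sphere are accessible; the atom's
    area is the accessible fraction times the inflated-sphere area.  A
    residue's SASA is the sum over its atoms.
    """
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    coords, rads, owners = _atom_radii(model, radii or VDW_RADII, ca_only_radius)
    unit = golden_spiral(n_points)
    inflated = rads + probe
    n_atoms = len(coords)
    per_residue = np.zeros(len(model.residues))
    for a in range(n_atoms):
        center, R = coords[a], inflated[a]
        d = np.linalg.norm(coords - center, axis=1)
        nbrs = np.where((d < R + inflated) & (np.arange(n_atoms) != a))[0]
        pts = center + R * unit
        accessible = np.ones(n_points, dtype=bool)
        for b in nbrs:
            accessible &= (
                np.linalg.norm(pts - coords[b], axis=1) >= inflated[b]
            )
            if not accessible.any():
                break
        area = 4.0 * math.pi * R * R * accessible.mean()
        per_residue[owners[a]] += area
    return SasaProfile(values=per_residue, probe=probe, n_points=n_points)


def binarize_active_site(prob: float) -> int:
    """1 iff the calibrated ligand-binding probability is strictly > 0.5."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"active-site probability {prob} outside [0, 1]")
    return int(prob > 0.5)


@dataclass(frozen=True)
class ReferenceEnergyTable:
    """Unfolded-state reference energy per amino acid (score units)."""

    energies: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.energies) != 20:
            raise ValueError(
                f"reference-energy table needs exactly 20 entries, "
                f"got {len(self.energies)}"
            )
        for aa, e in self.energies.items():
            if not np.isfinite(e):
                raise ValueError(f"non-finite reference energy for {aa!r}")

    def __getitem__(self, aa: str) -> float:
        try:
            return float(self.energies[aa])
        except KeyError:
            raise KeyError(f"unknown amino acid {aa!r}") from None

    @classmethod
    def from_tsv(cls, tsv_text: str) -> "ReferenceEnergyTable":
        df = pd.read_csv(StringIO(tsv_text), sep="\t")
        if not {"amino_acid", "energy"} <= set(df.columns):
            raise ValueError("expected columns: amino_acid, energy")
        return cls(dict(zip(df["amino_acid"], df["energy"].astype(float))))

    @classmethod
    def default(cls) -> "ReferenceEnergyTable":
        """The shipped synthetic table (see data/reference_energies_synthetic.tsv)."""
        text = (
            resources.files("savpred")
            .joinpath("data/reference_energies_synthetic.tsv")
            .read_text()
        )
        return cls.from_tsv(text)


def reference_energy_features(
    wt_aa: str, mut_aa: str, table: ReferenceEnergyTable
) -> Tuple[float, float]:
    """(mutant reference energy, mutant-minus-wild-type difference)."""
    mut = table[mut_aa]
    return mut, mut - table[wt_aa]


@dataclass(frozen=True)
class ExternalFeatureRecord:
    """Tool-derived feature values for one SAV; any field may be missing."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    ddg_fold: Optional[float] = None
    wt_psic: Optional[float] = None
    delta_psic: Optional[float] = None
    delta_e_epistatic: Optional[float] = None
    fis: Optional[float] = None
    mutant_ssf: Optional[float] = None
    active_site_prob: Optional[float] = None

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


_NUMERIC_COLUMNS = (
    "ddg_fold",
    "wt_psic",
    "delta_psic",
    "delta_e_epistatic",
    "fis",
    "mutant_ssf",
    "active_site_prob",
)


def ingest_external_features(tsv_text: str) -> List[ExternalFeatureRecord]:
    """Parse a tool-derived feature TSV into records keyed by SAV.

    Required key columns: protein_id, position, wt_aa, mut_aa.  Recognized
    numeric columns are listed in the record type; unparseable cells become
    missing values (counted and logged) and duplicate keys raise.
    """
    df = pd.read_csv(
        StringIO(tsv_text), sep="\t", dtype=str, keep_default_na=False
    )
    required = {"protein_id", "position", "wt_aa", "mut_aa"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")

    records = []
    seen: Dict[Tuple, int] = {}
    n_coerced = 0
    for idx, row in df.iterrows():
        values = {}
        for col in _NUMERIC_COLUMNS:
            if col not in df.columns:
                continue
            cell = row[col].strip()
            if not cell:
                continue
            try:
                values[col] = float(cell)
            except ValueError:
                n_coerced += 1
        rec = ExternalFeatureRecord(
            protein_id=row["protein_id"],
            position=int(row["position"]),
            wt_aa=row["wt_aa"],
            mut_aa=row["mut_aa"],
            **values,
        )
        if rec.key in seen:
            dupes = [k for k, n in seen.items() if n > 0]
            raise ValueError(f"duplicate SAV keys in feature table: {rec.key}")
        seen[rec.key] = idx
        records.append(rec)
    if n_coerced:
        logger.info(
            "ingest_external_features: %d unparseable numeric cells "
            "treated as missing",
            n_coerced,
        )
    return records


def sasa_to_tsv(model: StructureModel, profile: SasaProfile) -> str:
    """TSV dump: chain, residue number, sasa."""
    lines = ["chain\tresidue_number\tsasa"]
    for k, res in enumerate(model.residues):
        lines.append("%s\t%d\t%.10g" % (res.chain_id, res.number, profile.values[k]))
    return "\n".join(lines) + "\n"
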