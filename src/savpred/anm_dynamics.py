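"""Anisotropic network model (ANM) dynamics features from Calpha traces.

An elastic network over Calpha atoms: residue pairs within a cutoff are
connected by Hookean springs of constant gamma, giving a 3N x 3N Hessian
whose nonzero eigenmodes approximate equilibrium fluctuations.  Four
per-residue features feed the classifier:

* MSD - mean squared displacement, the trace of a residue's 3x3 diagonal
  block of the Hessian pseudo-inverse (covariance), in units of 1/gamma;
* mechanical stiffness - inverse mean-square distance fluctuation toward
  each partner residue, averaged over partners (resistance to pulling);
* effectiveness / sensitivity - perturbation-response scanning (PRS) row
  and column means: how strongly perturbing a residue moves the rest of
  the structure, and how strongly a residue responds to perturbations
  elsewhere.

Defaults (cutoff 15 A, gamma 1, zero-mode tolerance 1e-8 * max eigenvalue)
follow standard ANM practice.  A connected, non-collinear structure has
exactly six zero modes (rigid translations and rotations); collinear beads
have five.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "AnmModel",
    "DynamicsProfile",
    "parse_ca_coords",
    "build_anm",
    "msd_profile",
    "stiffness_profile",
    "prs_profile",
    "compute_dynamics",
    "dynamics_to_tsv",
]

ZERO_MODE_RTOL = 1e-8


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # Angstrom, shape (3,)

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float)
        object.__setattr__(self, "coord", c)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"bad coordinate for atom {self.name!r}")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int
    name: str
    ca: np.ndarray  # Calpha coordinate
    atoms: Tuple[Atom, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.ca, dtype=float)
        object.__setattr__(self, "ca", c)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"bad Calpha coordinate for residue {self.number}")


@dataclass(frozen=True)
class StructureModel:
    """Ordered residue records with Calpha coordinates (and full atoms)."""

    residues: Tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("structure has no residues")
        seen = set()
        for r in self.residues:
            key = (r.chain_id, r.number)
            if key in seen:
                raise ValueError(f"duplicate residue number {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """(N, 3) Calpha coordinate array."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def residue_numbers(self) -> Tuple[int, ...]:
        return tuple(r.number for r in self.residues)


def _pick_altloc(atom):
    """Resolve a possibly disordered atom: highest occupancy, ties -> 'A'."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    return max(
        children,
        key=lambda a: (a.get_occupancy() or 0.0, a.get_altloc() == "A"),
    )


def parse_ca_coords(pdb_text: str, chain: str = "first") -> StructureModel:
    """Parse PDB ATOM records into a :class:`StructureModel`.

    Keeps one Calpha per residue, ordered by residue number; altlocs resolve
    to the highest-occupancy conformer (ties prefer 'A'); HETATM records and
    residues without a Calpha are ignored.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("m", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ValueError("no coordinates found in PDB text")
    chains = list(models[0])
    if not chains:
        raise ValueError("no chains found in PDB text")
    if chain == "first":
        target = chains[0]
    else:
        by_id = {c.id: c for c in chains}
        if chain not in by_id:
            raise KeyError(
                f"chain {chain!r} not present (available: {sorted(by_id)})"
            )
        target = by_id[chain]

    residues = []
    for res in target:
        if res.id[0].strip():  # HETATM / water
            continue
        ca = None
        atoms = []
        for atom in res:
            picked = _pick_altloc(atom)
            elem = (picked.element or "").strip().upper()
            atoms.append(Atom(picked.get_name(), elem, np.array(picked.coord)))
            if picked.get_name() == "CA":
                ca = np.array(picked.coord, dtype=float)
        if ca is None:
            continue
        residues.append(
            Residue(
                chain_id=target.id,
                number=int(res.id[1]),
                name=res.get_resname(),
                ca=ca,
                atoms=tuple(atoms),
            )
        )
    if not residues:
        raise ValueError("no Calpha atoms found in PDB text")
    residues.sort(key=lambda r: r.number)
    return StructureModel(tuple(residues))


@dataclass(frozen=True)
class AnmModel:
    """ANM Hessian with its eigendecomposition.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the orthonormal mode
    for eigenvalue k.  ``n_zero_modes`` counts eigenvalues below
    ``ZERO_MODE_RTOL * max(eigenvalue)``.
    """

    hessian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int
    cutoff: float
    gamma: float

    @property
    def n_residues(self) -> int:
        return self.hessian.shape[0] // 3

    def covariance(self) -> np.ndarray:
        """Hessian pseudo-inverse from the nonzero modes (units 1/gamma)."""
        nz = self.n_zero_modes
        if nz >= len(self.eigenvalues):
            raise ValueError("no nonzero modes: network is fully degenerate")
        lam = self.eigenvalues[nz:]
        V = self.eigenvectors[:, nz:]
        return (V / lam) @ V.T


def build_anm(
    model: StructureModel, cutoff: float = 15.0, gamma: float = 1.0
) -> AnmModel:
    """Build the ANM Hessian and diagonalize it.

    The off-diagonal 3x3 superblock for a pair (i, j) within the cutoff is
    ``-gamma * r_hat r_hat^T``; diagonal superblocks are the negative row
    sums, so each row of superblocks sums to zero.  A disconnected network
    (more than six zero modes) triggers a warning rather than an error.
    """
    X = model.coords()
    n = len(X)
    if n < 2:
        raise ValueError("ANM needs at least 2 residues")
    H = np.zeros((3 * n, 3 * n))
    diff = X[:, None, :] - X[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    ii, jj = np.where((dist <= cutoff) & (dist > 0))
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        u = diff[j, i] / dist[i, j]
        block = -gamma * np.outer(u, u)
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    evals, evecs = np.linalg.eigh(H)
    tol = ZERO_MODE_RTOL * max(float(evals.max()), 1e-300)
    n_zero = int(np.sum(evals < tol))
    if n_zero > 6:
        warnings.warn(
            f"elastic network is disconnected: {n_zero} zero modes "
            f"(cutoff {cutoff} A)",
            stacklevel=2,
        )
    return AnmModel(
        hessian=H,
        eigenvalues=evals,
        eigenvectors=evecs,
        n_zero_modes=n_zero,
        cutoff=cutoff,
        gamma=gamma,
    )


def msd_profile(anm: AnmModel) -> np.ndarray:
    """Per-residue mean squared displacement (trace of the 3x3 covariance
    diagonal superblock), computed mode-wise with zero modes excluded."""
    nz = anm.n_zero_modes
    if nz >= len(anm.eigenvalues):
        raise ValueError("no nonzero modes available for MSD")
    lam = anm.eigenvalues[nz:]
    V = anm.eigenvectors[:, nz:]
    per_coord = (V**2 / lam).sum(axis=1)  # diag of the pseudo-inverse
    return per_coord.reshape(anm.n_residues, 3).sum(axis=1)


def stiffness_profile(model: StructureModel, anm: AnmModel) -> np.ndarray:
    """Per-residue mechanical stiffness.

    The effective force constant for a pair is the inverse mean-square
    fluctuation of the inter-residue distance,
    ``kappa_ij = [sum_k lambda_k^-1 ((u_kj - u_ki) . r_hat_ij)^2]^-1``,
    and a residue's stiffness is the mean of kappa over all partners.
    Scales linearly with gamma.
    """
    X = model.coords()
    n = len(X)
    if n < 2:
        raise ValueError("stiffness needs at least 2 residues")
    nz = anm.n_zero_modes
    lam = anm.eigenvalues[nz:]
    V = anm.eigenvectors[:, nz:].reshape(n, 3, -1)
    kappa = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rij = X[j] - X[i]
            d = np.linalg.norm(rij)
            if d == 0:
                raise ValueError(f"coincident residues {i} and {j}")
            u = rij / d
            proj = u @ (V[j] - V[i])  # per-mode distance-fluctuation amplitude
            var = float((proj**2 / lam).sum())
            kappa[i, j] = kappa[j, i] = np.inf if var == 0 else 1.0 / var
    return kappa.sum(axis=1) / (n - 1)


def prs_profile(anm: AnmModel) -> Tuple[np.ndarray, np.ndarray]:
    """Perturbation-response scanning effectiveness and sensitivity.

    The response of residue j to a unit perturbation at residue i is the
    squared Frobenius norm of the (i, j) 3x3 covariance superblock; rows are
    normalized by their diagonal, effectiveness is the mean of row i over
    j != i and sensitivity the mean of column j over i != j.
    """
    C = anm.covariance()
    n = anm.n_residues
    Cr = C.reshape(n, 3, n, 3)
    P = (Cr**2).sum(axis=(1, 3))
    diag = np.diag(P)
    if np.any(diag <= 0):
        raise ValueError("zero diagonal in perturbation-response matrix")
    norm = P / diag[:, None]  # norm[i, i] == 1
    effectiveness = (norm.sum(axis=1) - 1.0) / (n - 1)
    sensitivity = (norm.sum(axis=0) - 1.0) / (n - 1)
    return effectiveness, sensitivity


@dataclass(frozen=True)
class DynamicsProfile:
    """The four per-residue ANM features."""

    msd: np.ndarray
    stiffness: np.ndarray
    effectiveness: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.msd)
        for name in ("msd", "stiffness", "effectiveness", "sensitivity"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if len(v) != n:
                raise ValueError("profile vectors have unequal lengths")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"non-finite or negative values in {name}")


def compute_dynamics(
    model: StructureModel, cutoff: float = 15.0, gamma: float = 1.0
) -> DynamicsProfile:
    """Convenience wrapper: build the ANM and evaluate all four features."""
    anm = build_anm(model, cutoff=cutoff, gamma=gamma)
    eff, sens = prs_profile(anm)
    return DynamicsProfile(
        msd=msd_profile(anm),
        stiffness=stiffness_profile(model, anm),
        effectiveness=eff,
        sensitivity=sens,
    )


def dynamics_to_tsv(model: StructureModel, profile: DynamicsProfile) -> str:
    """TSV dump: chain, residue number, msd, stiffness, effectiveness, sensitivity."""
    lines = ["chain\tresidue_number\tmsd\tstiffness\teffectiveness\tsensitivity"]
    for k, res in enumerate(model.residues):
        lines.append(
            "%s\t%d\t%.10g\t%.10g\t%.10g\t%.10g"
            % (
                res.chain_id,
                res.number,
                profile.msd[k],
                profile.stiffness[k],
                profile.effectiveness[k],
                profile.sensitivity[k],
            )
        )
    return "\n".join(lines) + "\n"
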