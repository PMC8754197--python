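"""Assembly, labelling and validation of the 15-feature SAV matrix.

Each single amino acid variant (SAV) gets a fixed-order vector of fifteen
features: five sequence-based (variation number, epistatic energy change,
functional impact score, PSIC difference, wild-type PSIC), six
structure-based (folding free-energy change, SASA, mutant knowledge-based
potential, binarized active-site flag, mutant and delta unfolded-state
reference energies) and four dynamics-based (MSD, stiffness, effectiveness,
sensitivity).  Labels come from clinical-significance tables: the three
benign categories map to 0, the three pathogenic ones to 1, entries with
fewer than one review star are dropped.

Missing provider values are stored as NaN, never silently zero; imputation
fills them with the per-feature median computed strictly from training rows
so no test information leaks into the fill values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .anm_dynamics import DynamicsProfile, StructureModel
from .ortholog_phylo import AMINO_ACIDS
from .structure_features import (
    ExternalFeatureRecord,
    ReferenceEnergyTable,
    SasaProfile,
    binarize_active_site,
    reference_energy_features,
)
from .variation_number import VariationNumberProfile

__all__ = [
    "FEATURE_NAMES",
    "Sav",
    "FeatureMatrix",
    "StructureFeatures",
    "label_from_clinvar",
    "assemble",
    "impute",
    "pearson_matrix",
    "pca_cumulative_variance",
    "welch_ttest",
]

logger = logging.getLogger(__name__)

#: canonical feature order
FEATURE_NAMES: Tuple[str, ...] = (
    "variation_number",
    "delta_e_epistatic",
    "fis",
    "delta_psic",
    "wt_psic",
    "ddg_fold",
    "sasa",
    "mutant_ssf",
    "active_site",
    "mutant_ref_energy",
    "delta_ref_energy",
    "msd",
    "stiffness",
    "effectiveness",
    "sensitivity",
)

_KEY_NAMES = ("protein_id", "position", "wt_aa", "mut_aa")

_BENIGN = {"benign", "benign/likely benign", "likely benign"}
_PATHOGENIC = {"pathogenic", "pathogenic/likely pathogenic", "likely pathogenic"}

_VARIANT_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclass(frozen=True)
class Sav:
    """A single amino acid variant, e.g. R15K in some protein."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise ValueError(
                f"non-standard amino acid in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous variant {self.wt_aa}{self.position}{self.mut_aa}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based, got {self.position}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    @classmethod
    def from_string(cls, protein_id: str, variant: str,
                    label: Optional[int] = None) -> "Sav":
        m = _VARIANT_RE.match(variant.strip().upper())
        if not m:
            raise ValueError(f"cannot parse variant string {variant!r}")
        return cls(protein_id, int(m.group(2)), m.group(1), m.group(3), label)


class FeatureMatrix:
    """Rows of feature vectors keyed by SAV, with aligned labels.

    ``df`` is indexed by (protein_id, position, wt_aa, mut_aa); missing
    cells are NaN.  ``errors`` collects per-row assembly problems (e.g. a
    variant position beyond the protein length).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        labels: Optional[pd.Series] = None,
        errors: Optional[List[str]] = None,
    ):
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate SAV keys: {dupes}")
        self.df = df
        if labels is None:
            labels = pd.Series(np.nan, index=df.index)
        if not labels.index.equals(df.index):
            raise ValueError("labels not aligned with feature rows")
        self.labels = labels
        self.errors = list(errors or [])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> Tuple[str, ...]:
        return tuple(self.df.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def drop_features(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.df.drop(columns=list(names)),
                             self.labels, self.errors)

    def to_tsv(self) -> str:
        out = self.df.copy()
        out.insert(len(out.columns), "label", self.labels)
        return out.to_csv(sep="\t", float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, tsv_text: str) -> "FeatureMatrix":
        df = pd.read_csv(StringIO(tsv_text), sep="\t")
        df = df.set_index(list(_KEY_NAMES))
        labels = df.pop("label") if "label" in df.columns else None
        return cls(df, labels)


def label_from_clinvar(tsv_text: str) -> List[Sav]:
    """Labelled SAVs from a clinical-significance table.

    Required columns: protein_id, variant (e.g. ``A123B``),
    clinical_significance, review_stars.  Rows with fewer than one review
    star are dropped; significance maps case-insensitively (three benign
    categories -> 0, three pathogenic ones -> 1); unrecognized significance
    strings are dropped with a logged count.
    """
    df = pd.read_csv(StringIO(tsv_text), sep="\t", dtype=str,
                     keep_default_na=False)
    required = {"protein_id", "variant", "clinical_significance", "review_stars"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    savs: List[Sav] = []
    n_unrecognized = 0
    for _, row in df.iterrows():
        if int(row["review_stars"]) < 1:
            continue
        sig = row["clinical_significance"].strip().lower()
        if sig in _BENIGN:
            label = 0
        elif sig in _PATHOGENIC:
            label = 1
        else:
            n_unrecognized += 1
            continue
        savs.append(Sav.from_string(row["protein_id"], row["variant"], label))
    if n_unrecognized:
        logger.info(
            "label_from_clinvar: dropped %d rows with unrecognized "
            "clinical significance", n_unrecognized,
        )
    return savs


@dataclass(frozen=True)
class StructureFeatures:
    """Per-protein structure/dynamics values indexed by residue number."""

    residue_numbers: Tuple[int, ...]
    sasa: Optional[np.ndarray] = None
    msd: Optional[np.ndarray] = None
    stiffness: Optional[np.ndarray] = None
    effectiveness: Optional[np.ndarray] = None
    sensitivity: Optional[np.ndarray] = None

    @classmethod
    def from_profiles(
        cls,
        model: StructureModel,
        dynamics: Optional[DynamicsProfile] = None,
        sasa: Optional[SasaProfile] = None,
    ) -> "StructureFeatures":
        return cls(
            residue_numbers=model.residue_numbers,
            sasa=None if sasa is None else sasa.values,
            msd=None if dynamics is None else dynamics.msd,
            stiffness=None if dynamics is None else dynamics.stiffness,
            effectiveness=None if dynamics is None else dynamics.effectiveness,
            sensitivity=None if dynamics is None else dynamics.sensitivity,
        )

    def value(self, name: str, position: int) -> float:
        vec = getattr(self, name)
        if vec is None or position not in self.residue_numbers:
            return np.nan
        return float(vec[self.residue_numbers.index(position)])


def assemble(
    savs: Sequence[Sav],
    vn_profiles: Optional[Mapping[str, VariationNumberProfile]] = None,
    structure_features: Optional[Mapping[str, StructureFeatures]] = None,
    external: Optional[Sequence[ExternalFeatureRecord]] = None,
    ref_table: Optional[ReferenceEnergyTable] = None,
) -> FeatureMatrix:
    """Build the 15-column feature matrix, one row per SAV.

    Absent provider values become NaN; a variant position beyond the
    protein's variation-number profile is recorded in ``errors`` (the row is
    kept with the affected cells missing).  Duplicate SAV keys raise.
    """
    ext_by_key: Dict[Tuple, ExternalFeatureRecord] = {}
    for rec in external or ():
        ext_by_key[rec.key] = rec

    rows, keys, labels, errors = [], [], [], []
    seen = set()
    for sav in savs:
        if sav.key in seen:
            raise ValueError(f"duplicate SAV key {sav.key}")
        seen.add(sav.key)
        row = dict.fromkeys(FEATURE_NAMES, np.nan)

        if vn_profiles and sav.protein_id in vn_profiles:
            profile = vn_profiles[sav.protein_id]
            if 1 <= sav.position <= len(profile):
                row["variation_number"] = profile.value_at(sav.position)
            else:
                errors.append(
                    f"{sav.protein_id} {sav.wt_aa}{sav.position}{sav.mut_aa}: "
                    f"position beyond protein length {len(profile)}"
                )

        if structure_features and sav.protein_id in structure_features:
            sf = structure_features[sav.protein_id]
            for name in ("sasa", "msd", "stiffness", "effectiveness",
                         "sensitivity"):
                row[name] = sf.value(name, sav.position)

        rec = ext_by_key.get(sav.key)
        if rec is not None:
            for name in ("delta_e_epistatic", "fis", "delta_psic", "wt_psic",
                         "ddg_fold", "mutant_ssf"):
                v = getattr(rec, name)
                if v is not None:
                    row[name] = v
            if rec.active_site_prob is not None:
                row["active_site"] = binarize_active_site(rec.active_site_prob)

        if ref_table is not None:
            mut_e, delta_e = reference_energy_features(
                sav.wt_aa, sav.mut_aa, ref_table
            )
            row["mutant_ref_energy"] = mut_e
            row["delta_ref_energy"] = delta_e

        rows.append(row)
        keys.append(sav.key)
        labels.append(np.nan if sav.label is None else sav.label)

    index = pd.MultiIndex.from_tuples(keys, names=_KEY_NAMES)
    df = pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES))
    return FeatureMatrix(df, pd.Series(labels, index=index), errors)


def impute(matrix: FeatureMatrix, training_mask: Sequence[bool]) -> FeatureMatrix:
    """Fill missing cells with per-feature medians of the training rows only.

    Raises if any feature has no observed training value.  Idempotent on a
    matrix without missing cells.
    """
    mask = np.asarray(training_mask, dtype=bool)
    if mask.shape != (len(matrix),):
        raise ValueError("training mask length does not match matrix rows")
    train = matrix.df.loc[mask]
    medians = train.median()
    dead = medians.index[medians.isna()].tolist()
    if dead:
        raise ValueError(
            f"features with no observed training values: {dead}"
        )
    n_filled = int(matrix.df.isna().sum().sum())
    if n_filled:
        logger.info("impute: filled %d missing cells with training medians",
                    n_filled)
    return FeatureMatrix(matrix.df.fillna(medians), matrix.labels,
                         matrix.errors)


def pearson_matrix(matrix: FeatureMatrix, labels: pd.Series) -> pd.DataFrame:
    """Pearson correlations between all features and the label (16 x 16).

    Zero-variance features yield NaN rows/columns, flagged with a warning.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows for correlations")
    df = matrix.df.copy()
    df["label"] = np.asarray(labels, dtype=float)
    degenerate = df.columns[df.std(ddof=1) == 0].tolist()
    if degenerate:
        logger.warning("pearson_matrix: zero-variance columns %s are "
                       "undefined", degenerate)
    return df.corr(method="pearson")


def pca_cumulative_variance(matrix: FeatureMatrix) -> np.ndarray:
    """Cumulative explained-variance fractions of the standardized features.

    Features are z-scored first; the k-th entry is the fraction of total
    variance captured by the top-k principal components (nondecreasing,
    ending at 1).
    """
    X = matrix.df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute the matrix before PCA")
    std = X.std(axis=0, ddof=1)
    if np.all(std == 0):
        raise ValueError("constant matrix: PCA undefined")
    std = np.where(std == 0, 1.0, std)
    Z = (X - X.mean(axis=0)) / std
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    return np.cumsum(pca.explained_variance_ratio_)


def welch_ttest(group0: Sequence[float], group1: Sequence[float]):
    """Welch unequal-variance t-test, two-sided: returns (t, p, df).

    The sign follows mean(group0) - mean(group1), so passing pathogenic
    variation numbers first and neutral second yields a negative t when the
    pathogenic class is more conserved.  Two zero-variance groups with equal
    means return t = 0 by convention.
    """
    a = np.asarray(group0, dtype=float)
    b = np.asarray(group1, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, float(len(a) + len(b) - 2)
        raise ValueError("degenerate t-test: zero variance, unequal means")
    return t, p, dof
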