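"""Per-position variation numbers from ortholog trees.

The variation number of a reference position is the minimal number of
substitutions (Fitch parsimony count) of the corresponding alignment column
on the ortholog tree, min-max scaled to [0, 1] within each protein:
0 means high conservation, 1 means low conservation.  Columns where the
reference row carries a gap are skipped, so positions index the ungapped
reference sequence (1-based, matching SAV notation such as R15K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .ortholog_phylo import GAP, OrthologAlignment, PhyloTree, fitch_count

__all__ = [
    "VariationNumberProfile",
    "variation_profile",
    "minmax_scale",
    "vn_for_sav",
    "profile_to_tsv",
]


@dataclass(frozen=True)
class VariationNumberProfile:
    """Raw parsimony counts and scaled variation numbers for one protein."""

    protein_id: str
    wild_type: str  # ungapped reference sequence
    raw_counts: np.ndarray  # int, one per reference position
    scaled: np.ndarray  # float in [0, 1]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_counts, dtype=int)
        sc = np.asarray(self.scaled, dtype=float)
        object.__setattr__(self, "raw_counts", raw)
        object.__setattr__(self, "scaled", sc)
        if len(raw) != len(sc) or len(raw) != len(self.wild_type):
            raise ValueError("profile arrays and wild-type length disagree")
        if np.any(raw < 0):
            raise ValueError("negative parsimony counts")
        if len(sc) and (sc.min() < 0 or sc.max() > 1):
            raise ValueError("scaled variation numbers outside [0, 1]")

    def __len__(self) -> int:
        return len(self.raw_counts)

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(range(1, len(self) + 1))

    def value_at(self, position: int) -> float:
        return vn_for_sav(self, position)


def minmax_scale(raw_counts: Sequence[int]) -> np.ndarray:
    """Scale counts to [0, 1] by (x - min) / (max - min) per protein.

    An all-equal profile is uninformative and maps to all zeros (the maximal
    conservation reading).
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot scale an empty profile")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def variation_profile(
    aln: OrthologAlignment,
    tree: PhyloTree,
    protein_id: Optional[str] = None,
) -> VariationNumberProfile:
    """Per-reference-position parsimony counts, min-max scaled per protein.

    The tree's leaf set must equal the alignment's sequence ids.  Each
    alignment column where the reference is not a gap contributes one
    position; its raw count is the Fitch parsimony score of the column's
    leaf states (gap = 21st state).
    """
    if set(tree.leaf_labels) != set(aln.sequence_ids):
        raise ValueError(
            "tree leaves do not match alignment sequence ids: "
            f"{sorted(set(tree.leaf_labels) ^ set(aln.sequence_ids))}"
        )
    ref = aln.reference_row
    raw = []
    wt = []
    for j in range(aln.n_columns):
        if ref[j] == GAP:
            continue
        raw.append(fitch_count(tree, aln.column(j)))
        wt.append(ref[j])
    raw_arr = np.array(raw, dtype=int)
    return VariationNumberProfile(
        protein_id=protein_id or aln.reference_id,
        wild_type="".join(wt),
        raw_counts=raw_arr,
        scaled=minmax_scale(raw_arr),
    )


def vn_for_sav(profile: VariationNumberProfile, position: int) -> float:
    """Scaled variation number at a 1-based ungapped reference position."""
    if not 1 <= position <= len(profile):
        raise IndexError(
            f"position {position} out of range for protein "
            f"{profile.protein_id!r} of length {len(profile)}"
        )
    return float(profile.scaled[position - 1])


def profile_to_tsv(profile: VariationNumberProfile) -> str:
    """TSV dump: protein_id, position, wt_aa, raw_count, scaled_vn."""
    lines = ["protein_id\tposition\twt_aa\traw_count\tscaled_vn"]
    for pos in profile.positions:
        lines.append(
            "%s\t%d\t%s\t%d\t%.10g"
            % (
                profile.protein_id,
                pos,
                profile.wild_type[pos - 1],
                profile.raw_counts[pos - 1],
                profile.scaled[pos - 1],
            )
        )
    return "\n".join(lines) + "\n"
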