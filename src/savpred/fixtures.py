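"""Synthetic data generators with the statistical structure the pipeline assumes.

Every stage of the pipeline is testable without downloads:

* ortholog families evolved along a random binary tree, with designated
  conserved sites that never mutate and a ground-truth count of realized
  substitution events per site (parsimony lower-bounds it);
* idealized Calpha traces (alpha-helix, straight line, random coil) written
  as valid PDB ATOM records;
* class-conditional feature datasets whose variation-number columns follow
  beta laws moment-matched to the empirical class statistics (pathogenic
  mean 0.12 / variance 0.017, neutral mean 0.32 / variance 0.04), with
  configurable class shifts on the other features and plantable
  missingness in the tool-derived columns;
* DMS-style fitness tables as a strictly monotone transform of prediction
  scores plus Gaussian noise.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .feature_table import FEATURE_NAMES, FeatureMatrix
from .ortholog_phylo import AMINO_ACIDS, OrthologAlignment, PhyloTree

__all__ = [
    "FixtureSpec",
    "synth_ortholog_family",
    "synth_structure",
    "synth_feature_dataset",
    "synth_dms",
]

#: default class shifts (pathogenic mean minus neutral mean, in units of the
#: unit feature s.d.); the three planted informative tool-derived features
DEFAULT_SHIFTS: Dict[str, float] = {
    "delta_psic": 1.2,
    "fis": 0.8,
    "wt_psic": 0.6,
}

#: columns that in production come from third-party tools and may be missing
TOOL_DERIVED = (
    "delta_e_epistatic",
    "fis",
    "delta_psic",
    "wt_psic",
    "ddg_fold",
    "mutant_ssf",
    "active_site",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    n_proteins: int = 20
    n_orthologs: int = 30
    seq_length: int = 120
    conserved_fraction: float = 0.3
    substitution_rate: float = 0.05  # per-site, per-branch
    n_pathogenic: int = 2000
    n_neutral: int = 2000
    vn_pathogenic_mean: float = 0.12
    vn_pathogenic_var: float = 0.017
    vn_neutral_mean: float = 0.32
    vn_neutral_var: float = 0.04
    feature_shifts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHIFTS)
    )
    missingness: float = 0.0
    dms_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_orthologs", "seq_length",
                     "n_pathogenic", "n_neutral"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("conserved_fraction", "substitution_rate", "missingness"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dms_noise_sd < 0:
            raise ValueError("dms_noise_sd must be nonnegative")


def _random_join_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree as nested tuples of leaf indices."""
    nodes: List[object] = list(range(n_leaves))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def synth_ortholog_family(
    spec: FixtureSpec, seed: Optional[int] = None
) -> Tuple[OrthologAlignment, np.ndarray, PhyloTree]:
    """Evolve an ortholog family along a random binary tree.

    Designated conserved sites (the first ``conserved_fraction`` share of
    positions) never mutate; each other site mutates independently on each
    branch with probability ``substitution_rate``.  Returns the gapless
    alignment (reference ``SEQ0``), the realized number of substitution
    events per site, and the true generating tree (parsimony counts on that
    tree lower-bound the realized events; a re-estimated tree need not).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.seq_length
    n = spec.n_orthologs
    aa = np.array(list(AMINO_ACIDS))
    n_conserved = int(round(spec.conserved_fraction * L))
    mutable = np.zeros(L, dtype=bool)
    mutable[n_conserved:] = True

    root_seq = rng.choice(len(aa), size=L)
    counts = np.zeros(L, dtype=int)
    leaves: Dict[int, np.ndarray] = {}

    def _evolve(node, seq):
        child = seq.copy()
        hit = mutable & (rng.random(L) < spec.substitution_rate)
        for site in np.where(hit)[0]:
            old = child[site]
            child[site] = rng.choice(
                [s for s in range(len(aa)) if s != old]
            )
            counts[site] += 1
        if isinstance(node, tuple):
            for sub in node:
                _evolve(sub, child)
        else:
            leaves[node] = child

    tree = _random_join_tree(n, rng)
    if isinstance(tree, tuple):
        for sub in tree:
            _evolve(sub, root_seq)
    else:
        leaves[tree] = root_seq.copy()

    ids = tuple(f"SEQ{i}" for i in range(n))
    rows = tuple("".join(aa[leaves[i]]) for i in range(n))
    aln = OrthologAlignment(ids, rows, reference_id="SEQ0")

    def _newick(node) -> str:
        if isinstance(node, tuple):
            return f"({_newick(node[0])}:1,{_newick(node[1])}:1)"
        return f"SEQ{node}"

    true_tree = PhyloTree.from_newick(_newick(tree) + ";")
    return aln, counts, true_tree


_PDB_ATOM = (
    "ATOM  {serial:>5d}  CA  ALA {chain}{resnum:>4d}    "
    "{x:>8.3f}{y:>8.3f}{z:>8.3f}  1.00  0.00           C"
)


def synth_structure(
    n_residues: int, geometry: str = "helix", seed: int = 0
) -> str:
    """Ideal Calpha trace written as PDB text.

    ``helix`` uses canonical alpha-helix parameters (rise 1.5 A per residue,
    100 degree turn, radius 2.3 A), giving consecutive Calpha distances of
    about 3.8 A; ``line`` places beads 3.8 A apart on the x-axis (a
    collinear structure with five rigid-body modes); ``random-coil`` is a
    3.8 A-step random walk.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    if geometry == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(100.0) * i
        coords[:, 0] = 2.3 * np.cos(theta)
        coords[:, 1] = 2.3 * np.sin(theta)
        coords[:, 2] = 1.5 * i
    elif geometry == "line":
        coords[:, 0] = 3.8 * np.arange(n_residues)
    elif geometry == "random-coil":
        steps = rng.normal(size=(n_residues - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords[1:] = np.cumsum(3.8 * steps, axis=0)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    lines = [
        _PDB_ATOM.format(
            serial=k + 1, chain="A", resnum=k + 1,
            x=coords[k, 0], y=coords[k, 1], z=coords[k, 2],
        )
        for k in range(n_residues)
    ]
    return "\n".join(lines + ["END"]) + "\n"


def _beta_params(mean: float, var: float) -> Tuple[float, float]:
    if not 0 < mean < 1:
        raise ValueError(f"beta mean {mean} outside (0, 1)")
    limit = mean * (1.0 - mean)
    if not 0 < var < limit:
        raise ValueError(
            f"infeasible beta moments: variance {var} must lie in (0, {limit:.4g})"
        )
    nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def synth_feature_dataset(
    spec: FixtureSpec, seed: Optional[int] = None
) -> Tuple[FeatureMatrix, pd.Series, pd.Series]:
    """Class-conditional feature matrix with labels and ortholog counts.

    Variation numbers are beta draws moment-matched per class; every other
    feature is unit-variance normal with the pathogenic mean shifted by
    ``feature_shifts`` (absent features shift 0); the binary active-site
    flag is Bernoulli(0.2 + shift) per class.  Missingness is planted
    uniformly at random in the tool-derived columns.  Ortholog counts are
    drawn per protein, independent of the labels.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n1, n0 = spec.n_pathogenic, spec.n_neutral
    n = n0 + n1
    y = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])

    a1, b1 = _beta_params(spec.vn_pathogenic_mean, spec.vn_pathogenic_var)
    a0, b0 = _beta_params(spec.vn_neutral_mean, spec.vn_neutral_var)
    vn = np.concatenate([
        rng.beta(a1, b1, size=n1),
        rng.beta(a0, b0, size=n0),
    ])

    shifts = dict(spec.feature_shifts)
    data: Dict[str, np.ndarray] = {"variation_number": vn}
    for name in FEATURE_NAMES:
        if name == "variation_number":
            continue
        shift = float(shifts.get(name, 0.0))
        if name == "active_site":
            p = np.where(y == 1, min(0.2 + shift, 1.0), 0.2)
            data[name] = (rng.random(n) < p).astype(float)
        else:
            data[name] = rng.normal(loc=shift * y, scale=1.0, size=n)

    if spec.missingness > 0:
        for name in TOOL_DERIVED:
            drop = rng.random(n) < spec.missingness
            data[name] = np.where(drop, np.nan, data[name])

    aa = list(AMINO_ACIDS)
    pids = [f"P{i % spec.n_proteins:03d}" for i in range(n)]
    wt_idx = rng.integers(0, 20, size=n)
    mut_idx = (wt_idx + rng.integers(1, 20, size=n)) % 20
    keys = [
        (pids[i], i // spec.n_proteins + 1, aa[wt_idx[i]], aa[mut_idx[i]])
        for i in range(n)
    ]
    index = pd.MultiIndex.from_tuples(
        keys, names=("protein_id", "position", "wt_aa", "mut_aa")
    )
    df = pd.DataFrame(data, index=index, columns=list(FEATURE_NAMES))
    labels = pd.Series(y.astype(float), index=index)

    protein_ids = sorted(set(pids))
    ortholog_counts = pd.Series(
        rng.integers(30, 400, size=len(protein_ids)), index=protein_ids
    )
    return FeatureMatrix(df, labels), labels, ortholog_counts


def synth_dms(
    model_scores: pd.Series, noise_sd: float = 0.1, seed: int = 0
) -> pd.Series:
    """DMS-style fitness scores: a strictly decreasing affine transform of
    the prediction scores (pathogenic variants lose fitness) plus Gaussian
    noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    s = model_scores.to_numpy(dtype=float)
    dms = 0.5 - 2.0 * s + rng.normal(scale=noise_sd, size=len(s)) if noise_sd \
        else 0.5 - 2.0 * s
    return pd.Series(dms, index=model_scores.index, name="dms_score")
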