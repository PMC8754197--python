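"""Ortholog alignments, distance trees and per-column parsimony counts.

The conservation feature at the core of this package is computed from a set
of orthologous protein sequences: a p-distance matrix over the aligned
orthologs, a neighbor-joining (NJ) tree built from it, and the minimal number
of substitutions per alignment column on that tree (Fitch small parsimony).
Gaps are treated as a 21st character state, so deletions in orthologs count
as evolutionary events.

Alignments are an input: sequences are expected to be pre-aligned (any
aligner can produce the FASTA; this package never shells out to one).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import dendropy
import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_VALID_CHARS = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "UNKNOWN",
    "OrthologAlignment",
    "DistanceMatrix",
    "PhyloTree",
    "parse_alignment",
    "p_distance",
    "neighbor_joining",
    "fitch_count",
]


@dataclass(frozen=True)
class OrthologAlignment:
    """Aligned ortholog residues: rows are species, columns are positions.

    Rows are uppercase strings over the 20 amino-acid letters plus ``X``
    (unknown) and ``-`` (gap).  ``reference_id`` names the human/query row
    whose ungapped coordinates define variant positions downstream.
    """

    sequence_ids: Tuple[str, ...]
    rows: Tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.sequence_ids):
            raise ValueError("sequence_ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.reference_id not in self.sequence_ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")
        for sid, row in zip(self.sequence_ids, self.rows):
            bad = set(row) - _VALID_CHARS
            if bad:
                raise ValueError(f"invalid residue characters {sorted(bad)} in {sid!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, sequence_id: str) -> str:
        try:
            return self.rows[self.sequence_ids.index(sequence_id)]
        except ValueError:
            raise KeyError(f"sequence id {sequence_id!r} not in alignment") from None

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_id)

    def column(self, j: int) -> Dict[str, str]:
        """Leaf-state map for alignment column ``j`` (0-based)."""
        return {sid: row[j] for sid, row in zip(self.sequence_ids, self.rows)}


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled pairwise distances; symmetric with a zero diagonal."""

    labels: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if np.any(d < 0):
            raise ValueError("negative distances")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")


class PhyloTree:
    """Unrooted tree over sequence labels, backed by a dendropy tree.

    NJ output is binary (every internal node has degree 3).  Branch lengths
    are nonnegative; negative NJ estimates are clamped to zero at build time.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    @property
    def leaf_labels(self) -> Tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter()
        )

    def _adjacency(self):
        """Undirected adjacency over dendropy nodes, plus leaf->node map."""
        adj: Dict[object, list] = {}
        leaves: Dict[str, object] = {}
        for nd in self._tree.preorder_node_iter():
            adj.setdefault(nd, [])
            for ch in nd.child_nodes():
                adj.setdefault(ch, [])
                adj[nd].append(ch)
                adj[ch].append(nd)
            if nd.is_leaf():
                leaves[nd.taxon.label] = nd
        return adj, leaves


def _sanitize_label(label: str) -> str:
    if label.replace("_", "").replace(".", "").isalnum():
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt(x: float) -> str:
    return "%.10g" % max(float(x), 0.0)


def parse_alignment(fasta_text: str, reference_id: str) -> OrthologAlignment:
    """Parse a pre-aligned multi-FASTA into an :class:`OrthologAlignment`.

    Rows are uppercased; ``.`` becomes a gap and any non-standard letter
    becomes ``X``.  Raises on empty input, ragged rows or a missing
    reference id.
    """
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    ids = tuple(r.id for r in records)
    rows = []
    for r in records:
        row = str(r.seq).upper().replace(".", GAP)
        row = "".join(c if c in _VALID_CHARS else UNKNOWN for c in row)
        rows.append(row)
    return OrthologAlignment(ids, tuple(rows), reference_id)


def p_distance(aln: OrthologAlignment) -> DistanceMatrix:
    """Pairwise p-distance: mismatches / comparable columns.

    A column is comparable for a pair when neither row carries a gap or an
    unknown (``X``) there.  Pairs with no comparable column get distance 1.
    """
    enc = np.array([list(r) for r in aln.rows])
    valid = (enc != GAP) & (enc != UNKNOWN)
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                dist = 1.0
            else:
                dist = float(np.sum(enc[i][comp] != enc[j][comp])) / n_comp
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(aln.sequence_ids), d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the lowest (i, j) index pair;
    negative branch-length estimates are clamped to 0.  For two taxa the
    result is the single edge with the observed distance split evenly.
    """
    d = np.asarray(dm.d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    labels = [_sanitize_label(l) for l in dm.labels]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        h = d[0, 1] / 2.0
        nwk = f"({labels[0]}:{_fmt(h)},{labels[1]}:{_fmt(h)});"
        return PhyloTree.from_newick(nwk)

    nodes = list(labels)  # newick fragments for active nodes
    D = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> lowest (i, j) pair among ties
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = D[i, j] - bi
        merged = f"({nodes[i]}:{_fmt(bi)},{nodes[j]}:{_fmt(bj)})"
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        dnew = np.maximum(dnew, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack(
            [
                np.hstack([D[np.ix_(keep, keep)], dnew[keep][:, None]]),
                np.hstack([dnew[keep], [0.0]]),
            ]
        )
        nodes = [nodes[k] for k in keep] + [merged]

    (a, b, c) = nodes
    ba = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    bb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    bc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    nwk = f"({a}:{_fmt(ba)},{b}:{_fmt(bb)},{c}:{_fmt(bc)});"
    return PhyloTree.from_newick(nwk)


def fitch_count(tree: PhyloTree, leaf_states: Mapping[str, str]) -> int:
    """Minimal number of state changes on the tree (small parsimony score).

    Runs Fitch's bottom-up set algorithm after rooting the unrooted tree at
    a leaf (deterministically, the lexicographically smallest label); the
    score is root-invariant.  The tree must be binary (internal degree <= 3);
    every leaf needs a state, and gap is an ordinary 21st state.
    """
    adj, leaves = tree._adjacency()
    missing = [lbl for lbl in leaves if lbl not in leaf_states]
    if missing:
        raise KeyError(f"missing leaf states for {sorted(missing)}")
    if any(len(nbrs) > 3 for nbrs in adj.values()):
        raise ValueError("fitch_count requires a binary (degree <= 3) tree")
    if len(leaves) == 1:
        return 0

    root_label = min(leaves)
    root = leaves[root_label]
    # iterative DFS to fix parents and a postorder
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        nd = stack.pop()
        order.append(nd)
        for nb in adj[nd]:
            if nb is not parent[nd]:
                parent[nb] = nd
                stack.append(nb)

    label_of = {node: lbl for lbl, node in leaves.items()}
    cost = 0
    sets: Dict[object, frozenset] = {}
    for nd in reversed(order):
        children = [nb for nb in adj[nd] if nb is not parent[nd]]
        if not children:
            sets[nd] = frozenset(leaf_states[label_of[nd]])
            continue
        s = None
        for ch in children:
            if s is None:
                s = sets[ch]
            else:
                inter = s & sets[ch]
                if inter:
                    s = inter
                else:
                    s = s | sets[ch]
                    cost += 1
        if nd is root:  # root is a leaf: reconcile its own state
            if leaf_states[label_of[nd]] not in s:
                cost += 1
        sets[nd] = s
    return cost
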