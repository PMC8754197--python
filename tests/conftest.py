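"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from savpred.anm_dynamics import Atom, Residue, StructureModel


# ---------------------------------------------------------------------------
# random unrooted binary trees + exhaustive small-parsimony oracle

def random_unrooted_binary(
    n_leaves: int, rng: np.random.Generator
) -> Tuple[str, List[Tuple[str, str]], List[str]]:
    """A random unrooted binary tree as (newick, edge list, leaf labels)."""
    labels = [f"L{i}" for i in range(n_leaves)]
    if n_leaves == 2:
        return (
            f"({labels[0]}:1,{labels[1]}:1);",
            [(labels[0], labels[1])],
            labels,
        )
    items = [(lbl, lbl) for lbl in labels]  # (node name, newick fragment)
    edges: List[Tuple[str, str]] = []
    nxt = 0
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        name = f"I{nxt}"
        nxt += 1
        (na, fa), (nb, fb) = items[i], items[j]
        edges += [(name, na), (name, nb)]
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append((name, f"({fa}:1,{fb}:1)"))
    root = f"I{nxt}"
    edges += [(root, name) for name, _ in items]
    newick = "(" + ",".join(f"{frag}:1" for _, frag in items) + ");"
    return newick, edges, labels


def exhaustive_parsimony(
    edges: Sequence[Tuple[str, str]],
    leaf_states: Dict[str, str],
    state_space: Sequence[str],
) -> int:
    """Brute-force minimum changes over all internal-node labelings."""
    nodes = {v for e in edges for v in e}
    internal = sorted(nodes - set(leaf_states))
    best = len(edges) + 1
    for combo in itertools.product(state_space, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign.update(leaf_states)
        cost = sum(assign[a] != assign[b] for a, b in edges)
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# random additive trees for neighbor-joining recovery

def random_tree_with_distances(
    n_leaves: int, rng: np.random.Generator
) -> Tuple[List[str], np.ndarray, str]:
    """Random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix: (labels, D, newick)."""
    labels = [f"T{i}" for i in range(n_leaves)]
    dist: Dict[frozenset, float] = {}
    # items: (newick fragment, {leaf: distance to this node})
    items = [(lbl, {lbl: 0.0}) for lbl in labels]

    def _join(parts):
        """Attach all parts to a new node with random branch lengths."""
        lens = rng.uniform(0.5, 1.5, size=len(parts))
        for (p1, e1), (p2, e2) in itertools.combinations(
            zip(parts, lens), 2
        ):
            for a, da in p1[1].items():
                for b, db in p2[1].items():
                    dist[frozenset((a, b))] = da + e1 + db + e2
        merged = {}
        for (frag, leafmap), e in zip(parts, lens):
            merged.update({a: da + e for a, da in leafmap.items()})
        frag = "(" + ",".join(
            f"{p[0]}:{e:.6f}" for p, e in zip(parts, lens)
        ) + ")"
        return frag, merged

    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = _join([items[i], items[j]])
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(merged)
    frag, _ = _join(items)
    newick = frag + ";"

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = dist[frozenset((a, b))]
    return labels, D, newick


def same_unrooted_topology(newick_a: str, newick_b: str) -> bool:
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    ta.is_rooted = tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb) == 0


# ---------------------------------------------------------------------------
# structure fixtures

def ca_model(coords) -> StructureModel:
    """Calpha-trace StructureModel from an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = tuple(
        Residue(
            chain_id="A",
            number=k + 1,
            name="ALA",
            ca=coords[k],
            atoms=(Atom("CA", "C", coords[k]),),
        )
        for k in range(len(coords))
    )
    return StructureModel(residues)


@pytest.fixture
def dimer() -> StructureModel:
    """Two beads 4 A apart on the x-axis."""
    return ca_model([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
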