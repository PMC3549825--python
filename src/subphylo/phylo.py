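"""Neighbor-joining tree construction and topology comparison.

Trees are thin wrappers around :mod:`dendropy` trees. Neighbor joining is the
standard Saitou–Nei agglomeration with deterministic tie handling (lowest
index pair) and PHYLIP-compatible treatment of negative branch-length
estimates (clamped to zero, deficit moved to the sibling branch). Tree
comparison offers the Robinson–Foulds symmetric bipartition difference and an
explicitly enumerated triplet distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from subphylo.distance import DistanceMatrix


@dataclass
class PhyloTree:
    """An unrooted leaf-labeled tree with non-negative branch lengths."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree=tree)

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", unquoted_underscores=True, suppress_rooting=True
            ).strip()
            + "\n"
        )

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    def clone(self) -> "PhyloTree":
        return PhyloTree(tree=self.tree.clone(depth=1))


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie breaking.

    Requires a symmetric matrix with a zero diagonal and at least 3 taxa.
    Ties in the Q criterion go to the lexicographically lowest index pair;
    negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling branch.
    """
    d = np.array(matrix.values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    r = d.shape[0]
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    namespace = dendropy.TaxonNamespace(matrix.labels)
    nodes = [
        dendropy.Node(taxon=namespace.get_taxon(label)) for label in matrix.labels
    ]
    while r > 3:
        sums = d.sum(axis=1)
        best = None
        best_pair = (0, 1)
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best:
                    best = q
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        merged = dendropy.Node()
        merged.add_child(nodes[i])
        merged.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.zeros((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [merged]
        d = d_new
        r -= 1

    center = dendropy.Node()
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        center.add_child(node)
        node.edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = center
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _nontrivial_bipartitions(t: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits as canonical leaf-label sets.

    Each internal edge yields the leaf set under it; the side not containing
    the anchor (lexicographically smallest label) is stored, which also merges
    the duplicate edge pair at a degree-2 root.
    """
    labels = t.leaf_labels
    n = len(labels)
    anchor = min(labels)
    splits: set[frozenset[str]] = set()
    for node in t.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        side = frozenset(labels - below) if anchor in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric difference of the non-trivial bipartition sets."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("trees have different leaf sets")
    return len(_nontrivial_bipartitions(t1) ^ _nontrivial_bipartitions(t2))


def _rooted_copy(
    t: PhyloTree, rooting: str, outgroup: Optional[str]
) -> dendropy.Tree:
    tree = t.clone().tree
    if rooting == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif rooting == "outgroup":
        if outgroup is None:
            raise ValueError("outgroup rooting requires an outgroup label")
        node = tree.find_node_with_taxon_label(outgroup)
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting policy {rooting!r}")
    return tree


def _triple_resolutions(tree: dendropy.Tree) -> dict:
    """Resolution of every leaf triple in a rooted tree.

    For a triple {a, b, c} the resolution is the pair whose MRCA is strictly
    deeper than the MRCA of the whole triple, or ``None`` if unresolved.
    """
    paths: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path[::-1]  # root -> leaf
    labels = sorted(paths)
    depth = {}
    for a, b in itertools.combinations(labels, 2):
        pa, pb = paths[a], paths[b]
        k = 0
        limit = min(len(pa), len(pb))
        while k < limit and pa[k] is pb[k]:
            k += 1
        depth[(a, b)] = k  # length of shared root path = MRCA depth + 1
    out = {}
    for a, b, c in itertools.combinations(labels, 3):
        dab = depth[(a, b)]
        dac = depth[(a, c)]
        dbc = depth[(b, c)]
        top = max(dab, dac, dbc)
        if [dab, dac, dbc].count(top) != 1:
            res = None
        elif dab == top:
            res = (a, b)
        elif dac == top:
            res = (a, c)
        else:
            res = (b, c)
        out[(a, b, c)] = res
    return out


def triplet_distance(
    t1: PhyloTree,
    t2: PhyloTree,
    rooting: str = "midpoint",
    outgroup: Optional[str] = None,
) -> float:
    """Fraction of leaf triples resolved differently by the two trees.

    Both trees are rooted by the same policy (midpoint by default, or a shared
    outgroup), then all C(n, 3) triples are enumerated explicitly.
    """
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("trees have different leaf sets")
    r1 = _triple_resolutions(_rooted_copy(t1, rooting, outgroup))
    r2 = _triple_resolutions(_rooted_copy(t2, rooting, outgroup))
    n_triples = len(r1)
    if n_triples == 0:
        return 0.0
    differing = sum(1 for key in r1 if r1[key] != r2[key])
    return differing / n_triples
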