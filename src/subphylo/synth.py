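"""Synthetic genome families with a known phylogeny.

A root sequence is drawn i.i.d. at a chosen GC content and evolved down a
preset (balanced or caterpillar) or user-supplied tree: each branch applies
per-site substitutions at a fixed rate (replacement uniform over the three
alternative bases) and optionally plants segmental events — inversions
(reversed segments) and complements (base-complemented segments) — so that the
match classes reported downstream have a controlled ground truth. Identical
seed and configuration give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from subphylo.phylo import PhyloTree
from subphylo.seqio import GenomeSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_leaves: int = 8
    shape: str = "balanced"  # "balanced" or "caterpillar"
    tree: Optional[PhyloTree] = None  # overrides shape/n_leaves when given
    root_length: int = 5000
    substitution_rate: float = 0.02
    n_inversions: int = 0
    inversion_length: tuple[int, int] = (100, 300)
    n_complements: int = 0
    complement_length: tuple[int, int] = (100, 300)
    gc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("GC content must be in [0, 1]")
        if self.root_length < 1:
            raise ValueError("root length must be >= 1")
        for lo, hi in (self.inversion_length, self.complement_length):
            if lo < 1 or hi < lo:
                raise ValueError("event length ranges must satisfy 1 <= lo <= hi")
        if self.tree is None and self.n_leaves < 3:
            raise ValueError("need at least 3 leaves for phylogeny recovery")
        if self.shape not in ("balanced", "caterpillar"):
            raise ValueError(f"unknown tree shape {self.shape!r}")


def preset_tree(shape: str, n_leaves: int, branch_length: float = 1.0) -> PhyloTree:
    """Deterministic topology with uniform branch lengths and leaves t1..tk."""
    labels = [f"t{i + 1}" for i in range(n_leaves)]

    def balanced(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{branch_length}"
        mid = (len(names) + 1) // 2
        return (
            f"({balanced(names[:mid])},{balanced(names[mid:])}):{branch_length}"
        )

    if shape == "balanced":
        mid = (n_leaves + 1) // 2
        newick = f"({balanced(labels[:mid])},{balanced(labels[mid:])});"
    elif shape == "caterpillar":
        clause = f"{labels[0]}:{branch_length}"
        for name in labels[1:-1]:
            clause = f"({clause},{name}:{branch_length}):{branch_length}"
        newick = f"({clause},{labels[-1]}:{branch_length});"
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    return PhyloTree.from_newick(newick)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    child = codes.copy()
    if rate > 0.0:
        mask = rng.random(len(child)) < rate
        k = int(mask.sum())
        if k:
            # uniform over the three alternative bases
            child[mask] = (child[mask] + rng.integers(1, 4, size=k)) % 4
    return child


def _plant_events(
    codes: np.ndarray,
    count: int,
    length_range: tuple[int, int],
    kind: str,
    rng: np.random.Generator,
) -> None:
    n = len(codes)
    lo, hi = length_range
    for _ in range(count):
        length = int(rng.integers(lo, hi + 1))
        length = min(length, n)
        start = int(rng.integers(0, n - length + 1))
        segment = codes[start : start + length]
        if kind == "inversion":
            codes[start : start + length] = segment[::-1]
        else:  # complement: A<->T, C<->G on the 0..3 encoding
            codes[start : start + length] = 3 - segment


def evolve_along_tree(
    cfg: SimulationConfig,
) -> tuple[list[GenomeSequence], PhyloTree]:
    """Simulate leaf genomes; returns (leaves in label order, true tree)."""
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree if cfg.tree is not None else preset_tree(cfg.shape, cfg.n_leaves)
    if len(tree.leaf_labels) < 3:
        raise ValueError("tree must have at least 3 leaves")
    p = np.array(
        [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
    )
    root = rng.choice(4, size=cfg.root_length, p=p).astype(np.int8)
    leaves: dict[str, str] = {}
    # deterministic preorder traversal of the dendropy tree
    stack = [(tree.tree.seed_node, root)]
    while stack:
        node, codes = stack.pop()
        if node.is_leaf():
            leaves[node.taxon.label] = (
                _BASES[codes.astype(np.uint8)].tobytes().decode("ascii")
            )
            continue
        for child in reversed(node.child_nodes()):
            evolved = _mutate(codes, cfg.substitution_rate, rng)
            _plant_events(
                evolved, cfg.n_inversions, cfg.inversion_length, "inversion", rng
            )
            _plant_events(
                evolved, cfg.n_complements, cfg.complement_length, "complement", rng
            )
            stack.append((child, evolved))
    out = [
        GenomeSequence(label=name, residues=leaves[name])
        for name in sorted(leaves, key=_natural_leaf_order)
    ]
    return out, tree


def _natural_leaf_order(label: str) -> tuple:
    if label.startswith("t") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, label)
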