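"""Similarity and distance measures built on the underlying subwords.

Per direction, every underlying subword contributes
``h_w * |w| * (|w| + 1) / 2`` — the sum of its suffix lengths, once per untied
occurrence in the scored sequence — and the total is averaged over the scored
sequence's length. The normalized form divides a base-4 logarithm of the
partner length by that similarity and subtracts a self-match correction so a
sequence is at distance zero from itself; the symmetric distance is the mean
of the two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from subphylo.matchstats import acs_similarity
from subphylo.seqio import (
    ExtendedSequence,
    GenomeSequence,
    MatchClass,
    SequenceLike,
    SymbolAllocator,
    build_extended,
)
from subphylo.underlying import UnderlyingSet, underlying_set


class IncomparablePairError(ValueError):
    """Two sequences share no underlying subword (similarity zero)."""


def _log4(x: float) -> float:
    return math.log(x, 4)


def ua_similarity(underlying: UnderlyingSet, s1: GenomeSequence) -> float:
    """Underlying-subword similarity of ``s1`` against the set's target.

    Sum over members of ``h_w^{s1} * |w| * (|w| + 1) / 2`` divided by ``|s1|``,
    where ``h_w^{s1}`` counts only untied occurrences in ``s1``.
    """
    total = 0
    for m in underlying.members:
        total += m.h_ref * m.length * (m.length + 1) // 2
    return total / s1.n


def ua_normalized_from_similarity(ua: float, len1: int, len2: int) -> float:
    """log4(|s2|) / similarity(s1, s2) - 2 * log4(|s1|) / (|s1| + 1)."""
    if ua <= 0:
        raise IncomparablePairError(
            "underlying similarity is zero; pair is incomparable"
        )
    return _log4(len2) / ua - 2.0 * _log4(len1) / (len1 + 1)


def _extend(seq: GenomeSequence, extended: bool) -> SequenceLike:
    if not extended:
        return seq
    return build_extended(seq)


def ua_normalized(
    s1: GenomeSequence,
    s2: GenomeSequence,
    underlying: Optional[UnderlyingSet] = None,
    extended: bool = True,
) -> float:
    """Directed, length-normalized similarity inverse for ``(s1, s2)``.

    ``|s2|`` in the numerator is the original sequence length even when the
    comparison ran against the extended form.
    """
    if underlying is None:
        underlying = underlying_set(s1, _extend(s2, extended))
    ua = ua_similarity(underlying, s1)
    return ua_normalized_from_similarity(ua, s1.n, s2.n)


def d_ua(
    s1: GenomeSequence,
    s2: GenomeSequence,
    extended: bool = True,
) -> float:
    """Symmetric distance: mean of the two directed normalized values."""
    return 0.5 * (
        ua_normalized(s1, s2, extended=extended)
        + ua_normalized(s2, s1, extended=extended)
    )


def acs_distance(
    s1: GenomeSequence,
    s2: GenomeSequence,
    extended: bool = False,
) -> float:
    """Symmetric distance built on the ACS similarity.

    This is a stand-in that mirrors the normalization used for the
    underlying-subword distance (log4 ratio plus self-match correction,
    averaged over both directions), not a published ACS distance formula.
    The self-similarity is the same closed form, so ``acs_distance(s, s)``
    is exactly zero.
    """

    def directed(a: GenomeSequence, b: GenomeSequence) -> float:
        sim = acs_similarity(a, _extend(b, extended))
        return ua_normalized_from_similarity(sim, a.n, b.n)

    return 0.5 * (directed(s1, s2) + directed(s2, s1))


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs distance matrix with ordered taxon labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self, precision: int = 6) -> str:
        """Square PHYLIP distance-matrix format (relaxed names)."""
        lines = [f"{len(self.labels)}"]
        width = max(10, max(len(l) for l in self.labels) + 2)
        for label, row in zip(self.labels, self.values):
            cells = "  ".join(f"{v:.{precision}f}" for v in row)
            lines.append(f"{label:<{width}}{cells}")
        return "\n".join(lines) + "\n"

    def to_tsv(self, precision: int = 6) -> str:
        lines = ["\t".join([""] + self.labels)]
        for label, row in zip(self.labels, self.values):
            lines.append(
                "\t".join([label] + [f"{v:.{precision}f}" for v in row])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [l for l in text.strip().splitlines() if l.strip()]
        k = int(lines[0].split()[0])
        labels: list[str] = []
        rows: list[list[float]] = []
        for line in lines[1 : 1 + k]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : 1 + k]])
        return cls(labels=labels, values=np.array(rows))


def distance_matrix(
    seqs: list[GenomeSequence],
    extended: bool = True,
    incomparable_factor: float = 2.0,
) -> DistanceMatrix:
    """All-pairs symmetric distances.

    Incomparable pairs (zero similarity in either direction) receive a ceiling
    of ``incomparable_factor`` times the largest finite off-diagonal value, so
    downstream neighbor joining stays well-defined.
    """
    k = len(seqs)
    if k < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    labels = [s.label for s in seqs]
    if len(set(labels)) != k:
        raise ValueError("duplicate sequence labels")
    values = np.zeros((k, k), dtype=float)
    incomparable: list[tuple[int, int]] = []
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d = d_ua(seqs[i], seqs[j], extended=extended)
            except IncomparablePairError:
                incomparable.append((i, j))
                continue
            values[i, j] = values[j, i] = d
    if incomparable:
        finite = [
            values[i, j]
            for i in range(k)
            for j in range(i + 1, k)
            if (i, j) not in incomparable
        ]
        ceiling = incomparable_factor * max(finite) if finite else 1.0
        for i, j in incomparable:
            values[i, j] = values[j, i] = ceiling
    return DistanceMatrix(labels=labels, values=values)


def match_class_stats(underlying: UnderlyingSet) -> dict:
    """Composition summary of an underlying set (match-class fractions of the
    untied target occurrences plus member-length statistics)."""
    classes = underlying.untied_target_classes()
    total = len(classes)
    counts = {cls: 0 for cls in MatchClass}
    for c in classes:
        counts[c] += 1
    lengths = [m.length for m in underlying.members]
    return {
        "n_members": len(underlying.members),
        "n_untied_target_occurrences": total,
        "fraction_direct": counts[MatchClass.DIRECT] / total if total else 0.0,
        "fraction_inversion": counts[MatchClass.INVERSION] / total if total else 0.0,
        "fraction_complement": counts[MatchClass.COMPLEMENT] / total if total else 0.0,
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "mean_length": sum(lengths) / len(lengths) if lengths else 0.0,
    }
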