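"""Matching statistics and the average-common-subword similarity.

``l[i]`` is the length of the longest subword starting at position ``i`` of
the reference that occurs somewhere in the other sequence. The vector can be
computed directly from the pair index, or reconstructed by superimposing
suffix-length scores of the irredundant common subwords over their reference
occurrences — both routes must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Iterator

from subphylo.index import build_index
from subphylo.seqio import GenomeSequence, SequenceLike

if TYPE_CHECKING:  # pragma: no cover
    from subphylo.irredundant import CommonSubword


@dataclass(frozen=True)
class MatchingStatisticsVector:
    """Per-position longest-match lengths for a reference sequence.

    ``values`` is 0-based internally; human-facing reports are 1-based.
    """

    reference: str
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.values)
        for i, v in enumerate(self.values):
            if not 0 <= v <= n - i:
                raise ValueError(f"l[{i + 1}] = {v} out of range [0, {n - i}]")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def __iter__(self) -> Iterator[int]:
        return iter(self.values)

    def at(self, position_1based: int) -> int:
        return self.values[position_1based - 1]


def matching_statistics(
    s1: GenomeSequence, s2: SequenceLike
) -> MatchingStatisticsVector:
    """Exact matching statistics of ``s1`` against ``s2`` (plain or extended)."""
    idx = build_index(s1, s2)
    return MatchingStatisticsVector(
        reference=s1.label, values=tuple(idx.matching_statistics_reference())
    )


def ms_from_subwords(
    subwords: Iterable["CommonSubword"], s1: GenomeSequence
) -> MatchingStatisticsVector:
    """Reconstruct the matching statistics from irredundant common subwords.

    Each subword ``w`` contributes the score ``|w| - j`` at offset ``j`` of
    every reference occurrence; the vector is the position-wise maximum.
    """
    n = s1.n
    values = [0] * n
    for sw in subwords:
        length = sw.length
        for start in sw.occurrences_ref:
            top = min(length, n - start)
            for j in range(top):
                score = length - j
                if score > values[start + j]:
                    values[start + j] = score
    return MatchingStatisticsVector(reference=s1.label, values=tuple(values))


def acs_similarity(s1: GenomeSequence, s2: SequenceLike) -> float:
    """Mean of the matching-statistics vector of ``s1`` against ``s2``."""
    ms = matching_statistics(s1, s2)
    return sum(ms.values) / s1.n
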