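"""Discovery of irredundant common subwords.

A common subword is irredundant when at least one of its occurrences, in
either sequence, is not covered by an occurrence of another common subword.
Discovery is two-phase on the pair index: phase 1 takes, for every suffix
position, the lowest both-colored ancestor (a right-maximal occurrence of the
word it spells); phase 2 keeps occurrences whose match length is not exceeded
by the match length one position to the left (left-maximality), and retains
the words with at least one occurrence that is both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from subphylo.index import PairIndex, build_index
from subphylo.seqio import (
    ExtendedSequence,
    GenomeSequence,
    MatchClass,
    SequenceLike,
)


@dataclass(frozen=True)
class Occurrence:
    """A located occurrence of a common subword.

    ``host`` is ``"ref"`` or ``"target"``; ``start`` is 0-based and host-local
    (for an extended target, local to the extended residues).
    """

    host: str
    start: int
    length: int
    match_class: MatchClass


class CommonSubword:
    """A word shared by the two inputs, with its occurrence starts per host.

    The word string is extracted lazily from the index when available, so
    discovery over long genomes does not materialize every spelled string.
    """

    __slots__ = (
        "length",
        "occurrences_ref",
        "occurrences_target",
        "right_maximal_witness",
        "left_maximal_witness",
        "_word",
        "_node",
        "_index",
    )

    def __init__(
        self,
        word: Optional[str] = None,
        occurrences_ref: Optional[list[int]] = None,
        occurrences_target: Optional[list[int]] = None,
        length: Optional[int] = None,
        node: int = -1,
        index: Optional[PairIndex] = None,
        right_maximal_witness: bool = True,
        left_maximal_witness: bool = True,
    ) -> None:
        if word is None and (length is None or index is None or node < 0):
            raise ValueError("either word or (length, node, index) is required")
        self._word = word
        self._node = node
        self._index = index
        self.length = len(word) if length is None else length
        self.occurrences_ref = list(occurrences_ref or [])
        self.occurrences_target = list(occurrences_target or [])
        if not self.occurrences_ref and not self.occurrences_target:
            raise ValueError("a common subword needs at least one occurrence")
        self.right_maximal_witness = right_maximal_witness
        self.left_maximal_witness = left_maximal_witness

    @property
    def word(self) -> str:
        if self._word is None:
            self._word = self._index.word(self._node)
        return self._word

    def first_occurrence_key(self) -> tuple[int, int]:
        """Earliest occurrence, scanning the reference first, then the target."""
        if self.occurrences_ref:
            return (0, self.occurrences_ref[0])
        return (1, self.occurrences_target[0])

    def occurrences(self, target: SequenceLike) -> list[Occurrence]:
        """Materialize occurrence records with match classes."""
        out = [
            Occurrence("ref", s, self.length, MatchClass.DIRECT)
            for s in self.occurrences_ref
        ]
        for s in self.occurrences_target:
            if isinstance(target, ExtendedSequence):
                cls = target.classify_position(s)
            else:
                cls = MatchClass.DIRECT
            out.append(Occurrence("target", s, self.length, cls))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CommonSubword({self.word!r}, ref={self.occurrences_ref}, "
            f"target={self.occurrences_target})"
        )


def find_irredundant(
    s1: GenomeSequence,
    s2: SequenceLike,
    index: Optional[PairIndex] = None,
) -> list[CommonSubword]:
    """Irredundant common subwords of ``(s1, s2)``.

    ``s2`` may be a plain genome (direct-only comparison) or an extended
    sequence. The returned subwords carry complete, sorted occurrence lists
    per host, and the backing index is kept on each subword so downstream
    selection can reuse its ancestor links. Output size is bounded by
    ``|s1| + |s2|``.
    """
    idx = index if index is not None else build_index(s1, s2)
    ms = idx.ms_concat()
    N = len(idx.concat)
    candidates: set[int] = set()
    for pos in range(N):
        length = ms[pos]
        if length < 1:
            continue
        # left-maximal: not covered by a match starting one position earlier.
        # Host boundaries need no special case: joiner/separator positions
        # carry a match length of 0.
        if pos > 0 and ms[pos] < ms[pos - 1]:
            continue
        candidates.add(idx.lowest_bicolored_ancestor(pos))
    out: list[CommonSubword] = []
    for node in sorted(candidates):
        ref_occ, tgt_occ = idx.occurrence_positions(node)
        out.append(
            CommonSubword(
                length=idx.sdepth[node],
                occurrences_ref=ref_occ,
                occurrences_target=tgt_occ,
                node=node,
                index=idx,
            )
        )
    return out
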