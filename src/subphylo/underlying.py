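"""Selection of the underlying subwords from the irredundant set.

Subwords are ranked by priority — longer first, ties broken by earliest first
occurrence (reference scanned before target) — and walked in that order. An
occurrence is *untied* when it does not overlap any untied occurrence already
accepted; because processing is in non-increasing length order, overlap can be
detected by testing only the two endpoint locations of the boolean coverage
vector Γ. A companion length table χ records suffix-position scores of the
accepted occurrences so that a truncated occurrence can be reassigned to the
longest irredundant prefix that still fits the uncovered region. A subword is
kept when it retains at least one untied occurrence in each sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from subphylo.index import PairIndex
from subphylo.irredundant import CommonSubword, find_irredundant
from subphylo.seqio import ExtendedSequence, GenomeSequence, MatchClass, SequenceLike

_REF, _TARGET = 0, 1


@dataclass(frozen=True, order=True)
class PriorityKey:
    """Total order for subword selection: longer wins, then earlier first
    occurrence. Distinct words never share both components."""

    neg_length: int
    first_occurrence: tuple[int, int]

    @classmethod
    def of(cls, subword: CommonSubword) -> "PriorityKey":
        return cls(-subword.length, subword.first_occurrence_key())


def priority_sort(subwords: Iterable[CommonSubword]) -> list[CommonSubword]:
    """Deterministic priority order: descending length, ties by ascending
    first occurrence (reference positions rank before target positions)."""
    return sorted(subwords, key=PriorityKey.of)


class CoverageState:
    """Γ boolean coverage vectors and χ length tables, one pair per host."""

    def __init__(self, n_ref: int, n_target: int) -> None:
        self.gamma = (bytearray(n_ref), bytearray(n_target))
        self.chi = ([0] * n_ref, [0] * n_target)

    def covered(self, host: int, pos: int) -> bool:
        return bool(self.gamma[host][pos])

    def claim(self, host: int, start: int, length: int) -> None:
        g, c = self.gamma[host], self.chi[host]
        for k in range(length):
            g[start + k] = 1
            c[start + k] = k + 1

    def release(self, host: int, start: int, length: int) -> None:
        g, c = self.gamma[host], self.chi[host]
        for k in range(length):
            g[start + k] = 0
            c[start + k] = 0


@dataclass
class UnderlyingMember:
    """An accepted subword with its untied occurrences per host."""

    subword: CommonSubword
    untied_ref: list[int]
    untied_target: list[int]

    @property
    def h_ref(self) -> int:
        return len(self.untied_ref)

    @property
    def h_target(self) -> int:
        return len(self.untied_target)

    @property
    def length(self) -> int:
        return self.subword.length

    @property
    def word(self) -> str:
        return self.subword.word


@dataclass
class UnderlyingSet:
    """The selected underlying subwords, in selection (priority) order."""

    members: list[UnderlyingMember]
    s1: GenomeSequence
    s2: SequenceLike

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def words(self) -> list[str]:
        return [m.word for m in self.members]

    def untied_target_classes(self) -> list[MatchClass]:
        """Match class of every untied target occurrence, in selection order."""
        out: list[MatchClass] = []
        for m in self.members:
            for pos in m.untied_target:
                if isinstance(self.s2, ExtendedSequence):
                    out.append(self.s2.classify_position(pos))
                else:
                    out.append(MatchClass.DIRECT)
        return out

    def total_untied_length(self, host: str = "ref") -> int:
        if host == "ref":
            return sum(m.h_ref * m.length for m in self.members)
        return sum(m.h_target * m.length for m in self.members)


class UnsortedInputError(ValueError):
    """select_underlying requires its input in priority order."""


def _check_sorted(subwords: Sequence[CommonSubword]) -> None:
    keys = [PriorityKey.of(sw) for sw in subwords]
    for a, b in zip(keys, keys[1:]):
        if b < a:
            raise UnsortedInputError(
                "subwords must be sorted by priority (use priority_sort)"
            )


def _shared_index(subwords: Sequence[CommonSubword]) -> Optional[PairIndex]:
    idx = subwords[0]._index
    if idx is None:
        return None
    for sw in subwords:
        if sw._index is not idx or sw._node < 0:
            return None
    return idx


def select_underlying(
    sorted_subwords: Sequence[CommonSubword],
    s1: GenomeSequence,
    s2: SequenceLike,
) -> UnderlyingSet:
    """Select the underlying subwords among ``sorted_subwords``.

    When the subwords carry a shared pair index (as produced by
    :func:`subphylo.irredundant.find_irredundant`), pending-occurrence lists
    are seeded through the nearest-irredundant-ancestor links and truncated
    occurrences are reassigned to ancestor prefixes. Without an index the same
    selection is computed by scanning every occurrence list in full; the two
    routes give identical results.
    """
    if not sorted_subwords:
        return UnderlyingSet(members=[], s1=s1, s2=s2)
    _check_sorted(sorted_subwords)
    idx = _shared_index(sorted_subwords)
    state = CoverageState(s1.n, len(s2))

    pending: dict[int, list[tuple[int, int]]] = {}
    if idx is not None:
        idx.mark_irredundant([sw._node for sw in sorted_subwords])
        seeds = idx.seed_lists()
        for pos, node in enumerate(seeds):
            if node == -1:
                continue
            host_is_ref, local = idx.split_pos(pos)
            pending.setdefault(node, []).append(
                (_REF if host_is_ref else _TARGET, local)
            )

    members: list[UnderlyingMember] = []
    for sw in sorted_subwords:
        length = sw.length
        if idx is not None:
            occ = pending.pop(sw._node, [])
            occ.sort()
        else:
            occ = [(_REF, i) for i in sorted(sw.occurrences_ref)] + [
                (_TARGET, i) for i in sorted(sw.occurrences_target)
            ]
        untied: tuple[list[int], list[int]] = ([], [])
        writes: list[tuple[int, int]] = []
        leftovers: list[tuple[int, int]] = []
        for h, i in occ:
            g = state.gamma[h]
            if g[i] or g[i + length - 1]:
                leftovers.append((h, i))
            else:
                # claim immediately: later occurrences of this same word must
                # tie against it, keeping untied occurrences disjoint
                state.claim(h, i, length)
                untied[h].append(i)
                writes.append((h, i))
        if untied[_REF] and untied[_TARGET]:
            members.append(
                UnderlyingMember(
                    subword=sw,
                    untied_ref=untied[_REF],
                    untied_target=untied[_TARGET],
                )
            )
        else:
            for h, i in writes:
                state.release(h, i, length)
            leftovers = occ
        if idx is None:
            continue
        # reassign still-uncovered occurrences to the longest irredundant
        # prefix that fits the free region: d = |w| - chi[i + |w| - 1]
        for h, i in leftovers:
            g = state.gamma[h]
            if g[i]:
                continue
            end = i + length - 1
            if g[end]:
                d = length - state.chi[h][end]
            else:
                d = length - 1
            if d < 1:
                continue
            u = idx.nearest_irredundant_prefix(sw._node, d)
            if u != -1:
                pending.setdefault(u, []).append((h, i))
    return UnderlyingSet(members=members, s1=s1, s2=s2)


def underlying_set(
    s1: GenomeSequence,
    s2: SequenceLike,
    index: Optional[PairIndex] = None,
) -> UnderlyingSet:
    """Full pipeline for one ordered pair: discover, rank, select."""
    subwords = find_irredundant(s1, s2, index=index)
    return select_underlying(priority_sort(subwords), s1, s2)
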