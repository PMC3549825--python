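"""Sequence input/output, alphabet normalization, and extended-sequence construction.

Genomes are kept as plain strings over ``A C G T`` plus *sentinel* symbols:
every non-ACGT input character is replaced by a globally unique code point from
the Unicode private-use area, so an ambiguous base can never take part in a
shared subword. The same pool supplies the separator symbols that join the
segments of an extended sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

DNA_BASES = "ACGT"
_DNA_SET = frozenset(DNA_BASES)
_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")

# Code-point pools for sentinels and separators (Unicode private-use planes,
# so they can never collide with a base). Sentinels come from plane 15 and
# separators from plane 16, keeping the two pools disjoint even for inputs
# with tens of thousands of ambiguous bases.
_PRIVATE_USE_START = 0xF0000
_SEPARATOR_START = 0x100000


class FastaError(ValueError):
    """Raised on malformed FASTA input (empty file, duplicate or empty record)."""


class MatchClass(str, Enum):
    """How an occurrence in an extended sequence relates to the source genome."""

    DIRECT = "direct"
    INVERSION = "inversion"
    COMPLEMENT = "complement"
    REVERSE_COMPLEMENT = "reverse_complement"


class SymbolAllocator:
    """Hands out private-use code points, each exactly once.

    One allocator is shared across a whole collection of sequences so that no
    sentinel or separator symbol is ever repeated between records.
    """

    def __init__(self, start: int = _PRIVATE_USE_START) -> None:
        self._next = start

    def take(self) -> str:
        symbol = chr(self._next)
        self._next += 1
        return symbol


def is_sentinel(ch: str) -> bool:
    """True for any symbol outside the ACGT alphabet (sentinel or separator)."""
    return ch not in _DNA_SET


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence with a normalized alphabet."""

    label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("sequence label must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.label!r} has zero length")
        if any("a" <= c <= "z" for c in self.residues):
            raise ValueError(
                f"sequence {self.label!r} contains lowercase residues; "
                "normalize with normalize_residues() first"
            )

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def reversed_residues(self) -> str:
        return self.residues[::-1]

    def complement_residues(self) -> str:
        """Base-pairing substitution A<->T, C<->G, *without* reversal."""
        return self.residues.translate(_COMPLEMENT_TABLE)


def normalize_residues(raw: str, allocator: SymbolAllocator) -> str:
    """Uppercase ``raw`` and replace every non-ACGT character by a fresh sentinel."""
    up = raw.upper()
    if _DNA_SET.issuperset(up):
        return up
    return "".join(c if c in _DNA_SET else allocator.take() for c in up)


@dataclass(frozen=True)
class ExtendedSequence:
    """A source genome concatenated with its reversal and its complement.

    The three segments appear in this exact order — direct, inversion
    (plain reversal), complement (A<->T / C<->G substitution, not reversed) —
    joined by unique separator symbols that belong to no segment and occur
    exactly once each. Optionally a fourth reverse-complement segment is
    appended (off by default).
    """

    source: GenomeSequence
    residues: str
    segment_bounds: tuple[tuple[int, int], ...]
    segment_classes: tuple[MatchClass, ...]

    @property
    def label(self) -> str:
        return self.source.label

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def segment_index_of(self, pos: int) -> int:
        for k, (lo, hi) in enumerate(self.segment_bounds):
            if lo <= pos < hi:
                return k
        raise ValueError(f"position {pos} is a separator or out of range")

    def classify_position(self, pos: int) -> MatchClass:
        """Match class of the segment containing 0-based position ``pos``."""
        return self.segment_classes[self.segment_index_of(pos)]

    def contains_interval(self, start: int, length: int) -> bool:
        """True if [start, start+length) lies entirely within one segment."""
        try:
            k = self.segment_index_of(start)
        except ValueError:
            return False
        lo, hi = self.segment_bounds[k]
        return start + length <= hi

    def map_occurrence(self, start: int, length: int) -> tuple[MatchClass, int]:
        """Map an occurrence interval back to 0-based source coordinates.

        Returns the match class and the start of the corresponding interval in
        the source genome (for inversion-type segments the interval is the one
        whose reversal was matched).
        """
        k = self.segment_index_of(start)
        lo, hi = self.segment_bounds[k]
        if start + length > hi:
            raise ValueError("occurrence spans a segment boundary")
        cls = self.segment_classes[k]
        local = start - lo
        if cls in (MatchClass.INVERSION, MatchClass.REVERSE_COMPLEMENT):
            return cls, self.source.n - local - length
        return cls, local


def build_extended(
    seq: GenomeSequence,
    allocator: SymbolAllocator | None = None,
    include_reverse_complement: bool = False,
) -> ExtendedSequence:
    """Concatenate ``seq`` with its reversal and complement, separator-joined."""
    if allocator is None:
        allocator = SymbolAllocator(start=_SEPARATOR_START)
    segments = [
        (seq.residues, MatchClass.DIRECT),
        (seq.reversed_residues(), MatchClass.INVERSION),
        (seq.complement_residues(), MatchClass.COMPLEMENT),
    ]
    if include_reverse_complement:
        segments.append(
            (seq.complement_residues()[::-1], MatchClass.REVERSE_COMPLEMENT)
        )
    parts: list[str] = []
    bounds: list[tuple[int, int]] = []
    classes: list[MatchClass] = []
    cursor = 0
    for i, (text, cls) in enumerate(segments):
        if i > 0:
            parts.append(allocator.take())
            cursor += 1
        parts.append(text)
        bounds.append((cursor, cursor + len(text)))
        classes.append(cls)
        cursor += len(text)
    return ExtendedSequence(
        source=seq,
        residues="".join(parts),
        segment_bounds=tuple(bounds),
        segment_classes=tuple(classes),
    )


SequenceLike = Union[GenomeSequence, ExtendedSequence]


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a multi-FASTA file into normalized :class:`GenomeSequence` records.

    Labels are the header up to the first whitespace. Residues are uppercased
    and every non-ACGT character becomes a globally unique sentinel. Errors
    (empty file, duplicate label, zero-length record) name the offending
    record.
    """
    path = Path(path)
    allocator = SymbolAllocator()
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        label = record.id
        if label in seen:
            raise FastaError(f"duplicate sequence label {label!r} in {path}")
        raw = str(record.seq)
        if not raw:
            raise FastaError(f"zero-length record {label!r} in {path}")
        seen.add(label)
        seqs.append(GenomeSequence(label=label, residues=normalize_residues(raw, allocator)))
    if not seqs:
        raise FastaError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(
    seqs: Iterable[GenomeSequence], path: str | os.PathLike, width: int = 70
) -> None:
    """Write sequences as FASTA; sentinel symbols are emitted as ``N``."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.label}\n")
            text = "".join(c if c in _DNA_SET else "N" for c in seq.residues)
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")
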