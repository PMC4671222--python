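"""Shared data model for reads, CIGAR strings and indel calls.

All internal coordinates are 0-based, half-open.  Conversion to the 1-based
conventions of SAM and VCF happens only at serialization time (see
:mod:`clipscan.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

CIGAR_OPS = "MIDSH=X"
#: ops that consume query bases
QUERY_OPS = frozenset("MIS=X")
#: ops that consume reference bases
REF_OPS = frozenset("MD=X")

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC beyond ACGTN not supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CigarError(ValueError):
    """Raised for malformed or structurally invalid CIGAR strings."""


@dataclass(frozen=True)
class CigarString:
    """A validated, normalized CIGAR: ordered ``(length, op)`` runs.

    Invariants enforced at construction: all lengths positive, no two
    adjacent runs share an op after normalization, and soft clips (S) only
    appear at the ends (outside of which only hard clips H may sit).
    """

    ops: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        merged = normalize_ops(self.ops)
        object.__setattr__(self, "ops", merged)
        _validate_clips(merged)

    def __str__(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.ops) or "*"

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self.ops)

    @property
    def query_length(self) -> int:
        """Number of query bases consumed (M, I, S, =, X)."""
        return sum(n for n, op in self.ops if op in QUERY_OPS)

    @property
    def reference_length(self) -> int:
        """Number of reference bases spanned (M, D, =, X)."""
        return sum(n for n, op in self.ops if op in REF_OPS)

    @property
    def left_clip(self) -> int:
        """Soft-clipped bases at the left end."""
        for n, op in self.ops:
            if op == "H":
                continue
            return n if op == "S" else 0
        return 0

    @property
    def right_clip(self) -> int:
        for n, op in reversed(self.ops):
            if op == "H":
                continue
            return n if op == "S" else 0
        return 0

    @property
    def clipped_length(self) -> int:
        return sum(n for n, op in self.ops if op == "S")


def normalize_ops(ops: Iterable[tuple[int, str]]) -> tuple[tuple[int, str], ...]:
    """Merge adjacent runs of the same op; reject non-positive lengths."""
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if op not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR op {op!r}")
        if n <= 0:
            raise CigarError(f"non-positive CIGAR run length {n}{op}")
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return tuple(merged)


def _validate_clips(ops: tuple[tuple[int, str], ...]) -> None:
    # S only at the ends (H may flank it); no H in the interior.
    core = [op for _, op in ops]
    i, j = 0, len(core)
    while i < j and core[i] == "H":
        i += 1
    while j > i and core[j - 1] == "H":
        j -= 1
    inner = core[i:j]
    if "H" in inner:
        raise CigarError("hard clip in CIGAR interior")
    if inner and inner[0] == "S":
        inner = inner[1:]
    if inner and inner[-1] == "S":
        inner = inner[:-1]
    if "S" in inner:
        raise CigarError("soft clip in CIGAR interior")


def parse_cigar(text: str) -> Optional[CigarString]:
    """Parse a SAM CIGAR string; ``"*"`` yields ``None`` (no alignment).

    Raises :class:`CigarError` naming the offset of the first malformed
    token.
    """
    if text == "*":
        return None
    ops: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {text!r} at offset {pos}")
        n = int(m.group(1))
        if n == 0:
            raise CigarError(f"zero-length CIGAR op at offset {m.start()} in {text!r}")
        ops.append((n, m.group(2)))
        pos = m.end()
    if pos != len(text) or not ops:
        raise CigarError(f"malformed CIGAR {text!r} at offset {pos}")
    return CigarString(tuple(ops))


@dataclass
class AlignedRead:
    """One read (or contig) alignment record, SAM-like but 0-based.

    ``seq`` is stored in reference orientation when mapped (as in SAM);
    ``quals`` is the Phred score list matching ``seq`` base for base.
    """

    name: str
    seq: str
    quals: bytes  # phred+33 encoded, same length as seq
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost reference coordinate
    mapq: int = 0
    cigar: Optional[CigarString] = None
    is_unmapped: bool = True
    is_reverse: bool = False
    is_read1: bool = False
    is_read2: bool = False
    is_secondary: bool = False
    is_duplicate: bool = False
    is_paired: bool = False
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.quals, str):
            self.quals = self.quals.encode()
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"{self.name}: qual length {len(self.quals)} != seq length {len(self.seq)}"
            )
        if not self.is_unmapped:
            self.check_query_consumption()

    def check_query_consumption(self) -> None:
        """Assert that the CIGAR consumes exactly len(seq) query bases."""
        if self.cigar is None:
            raise ValueError(f"{self.name}: mapped read without CIGAR")
        qlen = self.cigar.query_length
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.name}: CIGAR consumes {qlen} query bases, read has {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        if self.is_unmapped or self.pos is None or self.cigar is None:
            raise ValueError(f"{self.name}: unmapped read has no reference span")
        return self.pos + self.cigar.reference_length

    def phred_scores(self) -> list[int]:
        return [q - 33 for q in self.quals]


def clipped_fraction(read: AlignedRead) -> float:
    """Soft-clipped proportion of the read: total S length / read length."""
    if read.is_unmapped or read.cigar is None:
        raise ValueError(f"{read.name}: clipped_fraction undefined for unmapped read")
    if not read.seq:
        raise ValueError(f"{read.name}: empty sequence")
    return read.cigar.clipped_length / len(read.seq)


@dataclass(frozen=True, order=True)
class IndelCall:
    """A normalized VCF-style indel with support counts and provenance."""

    chrom: str
    pos: int  # 1-based VCF anchor position
    ref: str
    alt: str
    svtype: str = field(compare=False)  # "DEL" or "INS"
    size: int = field(compare=False)
    support: int = field(compare=False)
    depth: int = field(compare=False)
    source: str = field(compare=False)  # "reads", "contigs" or "reads,contigs"

    def __post_init__(self) -> None:
        if self.svtype == "DEL":
            if len(self.ref) != self.size + 1 or len(self.alt) != 1:
                raise ValueError(f"inconsistent DEL alleles at {self.chrom}:{self.pos}")
        elif self.svtype == "INS":
            if len(self.alt) != self.size + 1 or len(self.ref) != 1:
                raise ValueError(f"inconsistent INS alleles at {self.chrom}:{self.pos}")
        else:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.support > self.depth:
            raise ValueError(
                f"support {self.support} exceeds depth {self.depth} at {self.chrom}:{self.pos}"
            )

    def with_(self, **kw) -> "IndelCall":
        return replace(self, **kw)

    @property
    def breakpoint(self) -> int:
        """0-based coordinate of the first affected reference base.

        For a deletion this is the first deleted base; for an insertion the
        reference base before which new sequence is inserted.  Equal to the
        1-based VCF anchor position because the anchor sits one base left.
        """
        return self.pos
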