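"""Readers and writers for FASTA, FASTQ, SAM (text dialect), VCF and BED.

FASTA/FASTQ go through Biopython; SAM records through pysam.  VCF output is
written directly (the record model here is small), VCF input is parsed with
pysam.  BED is the 0-based half-open convention.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO

from .alignment_core import AlignedRead, IndelCall, parse_cigar

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{name: sequence}`` dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, bytes]]:
    """Load FASTQ (Phred+33) as ``(name, seq, qual_bytes)`` triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = bytes(q + 33 for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(reads: Iterable[tuple[str, str, bytes]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            q = qual.decode() if isinstance(qual, bytes) else qual
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# SAM

def _flags_of(read: AlignedRead) -> int:
    f = 0
    if read.is_paired:
        f |= FLAG_PAIRED
    if read.is_unmapped:
        f |= FLAG_UNMAPPED
    if read.is_reverse:
        f |= FLAG_REVERSE
    if read.is_read1:
        f |= FLAG_READ1
    if read.is_read2:
        f |= FLAG_READ2
    if read.is_secondary:
        f |= FLAG_SECONDARY
    if read.is_duplicate:
        f |= FLAG_DUP
    return f


def write_sam(
    reads: Iterable[AlignedRead],
    reference: dict[str, str] | dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write records as plain-text SAM, sorted by (chrom, pos).

    ``reference`` maps chromosome name to its sequence (or directly to its
    length), and defines the @SQ header order.
    """
    lengths = {
        name: (val if isinstance(val, int) else len(val)) for name, val in reference.items()
    }
    order = {name: i for i, name in enumerate(lengths)}
    mapped = [r for r in reads if not r.is_unmapped]
    unmapped = [r for r in reads if r.is_unmapped]
    mapped.sort(key=lambda r: (order.get(r.chrom, len(order)), r.pos, r.name))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in mapped + unmapped:
            if r.is_unmapped:
                rname, pos, mapq, cig = "*", 0, 0, "*"
            else:
                rname, pos, mapq, cig = r.chrom, r.pos + 1, r.mapq, str(r.cigar)
            fields = [
                r.name, str(_flags_of(r)), rname, str(pos), str(mapq), cig,
                "*", "0", "0", r.seq or "*", r.quals.decode() or "*",
            ]
            for tag, value in sorted(r.tags.items()):
                code = "i" if isinstance(value, int) else "Z"
                fields.append(f"{tag}:{code}:{value}")
            fh.write("\t".join(fields) + "\n")


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read SAM/BAM records into :class:`AlignedRead` (skips secondary/supplementary)."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            if rec.query_qualities is not None:
                quals = bytes(q + 33 for q in rec.query_qualities)
            else:
                quals = b"I" * len(seq)
            tags = {tag: val for tag, val in rec.get_tags()}
            out.append(
                AlignedRead(
                    name=rec.query_name,
                    seq=seq.upper(),
                    quals=quals,
                    chrom=None if rec.is_unmapped else rec.reference_name,
                    pos=None if rec.is_unmapped else rec.reference_start,
                    mapq=rec.mapping_quality,
                    cigar=None if rec.is_unmapped else parse_cigar(rec.cigarstring or "*"),
                    is_unmapped=rec.is_unmapped,
                    is_reverse=rec.is_reverse,
                    is_read1=rec.is_read1,
                    is_read2=rec.is_read2,
                    is_secondary=rec.is_secondary,
                    is_duplicate=rec.is_duplicate,
                    is_paired=rec.is_paired,
                    tags=tags,
                )
            )
    return out


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Indel type (DEL or INS)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed indel length">',
    '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Evidence branch (reads, contigs or reads,contigs)">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read or contig count">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth at the locus">',
]


def write_vcf(
    calls: Sequence[IndelCall],
    reference: dict[str, str],
    path: str | os.PathLike,
) -> None:
    """Write indel calls as VCF 4.2, verifying each REF allele against the FASTA.

    Calls must already be sorted by (chrom in reference order, pos).
    """
    order = {name: i for i, name in enumerate(reference)}
    keys = [(order.get(c.chrom, len(order)), c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos) in reference order")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clipscan\n")
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            chrom_seq = reference.get(call.chrom)
            if chrom_seq is None or call.pos < 1 or call.pos - 1 + len(call.ref) > len(chrom_seq):
                raise ValueError(f"anchor base unavailable for {call.chrom}:{call.pos}")
            expected = chrom_seq[call.pos - 1 : call.pos - 1 + len(call.ref)]
            if expected != call.ref:
                raise ValueError(
                    f"REF allele mismatch at {call.chrom}:{call.pos}: {call.ref!r} vs {expected!r}"
                )
            svlen = call.size if call.svtype == "INS" else -call.size
            info = (
                f"SVTYPE={call.svtype};SVLEN={svlen};SOURCE={call.source};"
                f"SUPPORT={call.support};DP={call.depth}"
            )
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | os.PathLike) -> list[IndelCall]:
    """Read a clipscan (or compatible indel-only) VCF back into calls."""
    out: list[IndelCall] = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            ref = rec.ref
            for alt in rec.alts or ():
                if len(alt) == len(ref):
                    continue  # not an indel
                svtype = "INS" if len(alt) > len(ref) else "DEL"
                size = abs(len(alt) - len(ref))
                info = rec.info
                support = int(info.get("SUPPORT", 1))
                depth = int(info.get("DP", max(support, 1)))
                out.append(
                    IndelCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        svtype=str(info.get("SVTYPE", svtype)),
                        size=size,
                        support=support,
                        depth=max(depth, support),
                        source=str(info.get("SOURCE", "reads")),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BED

def write_bed(
    intervals: Iterable[tuple],
    path: str | os.PathLike,
) -> None:
    """Write intervals as BED; each item is (chrom, start, end, *extra)."""
    with open(path, "w") as fh:
        for item in intervals:
            fh.write("\t".join(str(x) for x in item) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    """Read BED lines as (chrom, start, end, *extra-strings)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out
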