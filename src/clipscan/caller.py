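"""Deterministic evidence-based indel calling from refined alignments.

Indels are read directly off the I/D runs of the final read and contig
CIGARs, normalized to their left-aligned minimal VCF representation,
aggregated per distinct allele, filtered by support thresholds, and merged
across the two evidence branches into one final call set.  The read branch
requires ``min_support`` supporting reads and a minimum alternate-allele
fraction; the contig branch only requires an accepted contig alignment,
because a single assembled contig already condenses many reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .alignment_core import AlignedRead, IndelCall
from .softclip_breakpoint import DepthProfile


@dataclass(frozen=True)
class CallerParams:
    min_support: int = 3
    min_alt_fraction: float = 0.05
    min_size: int = 1
    left_align: bool = True
    min_contig_support: int = 1

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0 < self.min_alt_fraction <= 1):
            raise ValueError("min_alt_fraction must lie in (0, 1]")


@dataclass
class IndelEvidence:
    chrom: str
    pos: int  # 0-based anchor coordinate (base before the event)
    svtype: str
    size: int
    ref: str
    alt: str
    read_names: set[str] = field(default_factory=set)
    depth: int = 0

    @property
    def support(self) -> int:
        return len(self.read_names)


def normalize_indel(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    reference: Mapping[str, str],
) -> tuple[str, int, str, str]:
    """Left-align and minimalize a VCF-style indel (0-based anchor ``pos``).

    Shared trailing bases are shifted left against the reference; shared
    leading bases beyond the single anchor are stripped.  Pure indels only
    (one allele must be a prefix-anchored extension of the other).
    """
    seq = reference[chrom]
    if seq[pos : pos + len(ref_allele)] != ref_allele:
        raise ValueError(
            f"REF allele mismatch at {chrom}:{pos}: {ref_allele!r} vs reference"
        )
    ref, alt = ref_allele, alt_allele
    # strip shared suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-shift while both alleles end with the same base
    while len(ref) > 1 or len(alt) > 1:
        if ref[-1] == alt[-1] and pos > 0:
            prev = seq[pos - 1]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            break
    # strip shared prefix beyond the anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def extract_indel_evidence(
    records: Sequence[AlignedRead],
    reference: Mapping[str, str],
    depth: Optional[DepthProfile] = None,
    min_size: int = 1,
    left_align: bool = True,
) -> list[IndelEvidence]:
    """Collect per-allele indel evidence from CIGAR I/D runs.

    One evidence entry per distinct (chrom, normalized pos, type, size,
    allele); support counts distinct read names.  Records whose CIGAR is
    inconsistent with the reference are skipped.
    """
    table: dict[tuple, IndelEvidence] = {}
    for rec in records:
        if rec.is_unmapped or rec.cigar is None:
            continue
        seq = reference.get(rec.chrom)
        if seq is None:
            continue
        rpos = rec.pos
        qpos = 0
        for ln, op in rec.cigar:
            if op == "S":
                qpos += ln
            elif op == "I":
                if rpos == 0 or ln < min_size:
                    qpos += ln
                    continue
                anchor = rpos - 1
                ref_allele = seq[anchor]
                alt_allele = ref_allele + rec.seq[qpos : qpos + ln]
                _add(table, rec, reference, rec.chrom, anchor, ref_allele,
                     alt_allele, "INS", ln, left_align)
                qpos += ln
            elif op == "D":
                if rpos == 0 or ln < min_size or rpos + ln > len(seq):
                    rpos += ln
                    continue
                anchor = rpos - 1
                ref_allele = seq[anchor : anchor + ln + 1]
                alt_allele = seq[anchor]
                _add(table, rec, reference, rec.chrom, anchor, ref_allele,
                     alt_allele, "DEL", ln, left_align)
                rpos += ln
            elif op in "M=X":
                rpos += ln
                qpos += ln
            elif op == "H":
                pass
        # (N/P unused in this pipeline)
    out = sorted(table.values(), key=lambda e: (e.chrom, e.pos, e.size, e.alt))
    if depth is not None:
        for ev in out:
            ev.depth = max(depth.depth(ev.chrom, ev.pos), ev.support)
    else:
        for ev in out:
            ev.depth = ev.support
    return out


def _add(table, rec, reference, chrom, anchor, ref_allele, alt_allele, svtype, size, left_align):
    if left_align:
        try:
            chrom, anchor, ref_allele, alt_allele = normalize_indel(
                chrom, anchor, ref_allele, alt_allele, reference
            )
        except ValueError:
            return
    key = (chrom, anchor, svtype, size, ref_allele, alt_allele)
    ev = table.get(key)
    if ev is None:
        ev = table[key] = IndelEvidence(
            chrom=chrom, pos=anchor, svtype=svtype, size=size,
            ref=ref_allele, alt=alt_allele,
        )
    ev.read_names.add(rec.name)


def _evidence_to_call(ev: IndelEvidence, source: str) -> IndelCall:
    return IndelCall(
        chrom=ev.chrom,
        pos=ev.pos + 1,  # 1-based VCF anchor
        ref=ev.ref,
        alt=ev.alt,
        svtype=ev.svtype,
        size=ev.size,
        support=ev.support,
        depth=max(ev.depth, ev.support),
        source=source,
    )


def call_variants(
    read_records: Sequence[AlignedRead],
    contig_records: Sequence[AlignedRead],
    params: CallerParams,
    reference: Mapping[str, str],
) -> tuple[list[IndelCall], list[IndelCall]]:
    """Call indels independently on the read branch and the contig branch."""
    lengths = {name: len(seq) for name, seq in reference.items()}

    read_calls: list[IndelCall] = []
    if read_records:
        depth = DepthProfile.from_reads(read_records, lengths)
        for ev in extract_indel_evidence(read_records, reference, depth,
                                         params.min_size, params.left_align):
            if ev.support < params.min_support:
                continue
            if ev.support / ev.depth < params.min_alt_fraction:
                continue
            read_calls.append(_evidence_to_call(ev, "reads"))

    contig_calls: list[IndelCall] = []
    if contig_records:
        depth = DepthProfile.from_reads(contig_records, lengths)
        for ev in extract_indel_evidence(contig_records, reference, depth,
                                         params.min_size, params.left_align):
            if ev.support < params.min_contig_support:
                continue
            contig_calls.append(_evidence_to_call(ev, "contigs"))

    return read_calls, contig_calls


def merge_vcfs(
    vcf_reads: Sequence[IndelCall], vcf_contigs: Sequence[IndelCall]
) -> list[IndelCall]:
    """Union of the two branches; identical alleles collapse into one record.

    A collapsed record reports SOURCE "reads,contigs" and the larger of the
    two support counts.  Inputs must each be sorted by (chrom, pos).
    """
    for calls in (vcf_reads, vcf_contigs):
        keys = [(c.chrom, c.pos) for c in calls]
        if keys != sorted(keys):
            raise ValueError("merge_vcfs requires sorted inputs")
    merged: dict[tuple, IndelCall] = {}
    for call in list(vcf_reads) + list(vcf_contigs):
        key = (call.chrom, call.pos, call.ref, call.alt)
        prev = merged.get(key)
        if prev is None:
            merged[key] = call
        elif prev.source != call.source:
            merged[key] = prev.with_(
                source="reads,contigs",
                support=max(prev.support, call.support),
                depth=max(prev.depth, call.depth,
                          max(prev.support, call.support)),
            )
        else:
            merged[key] = prev.with_(
                support=max(prev.support, call.support),
                depth=max(prev.depth, call.depth),
            )
    return sorted(merged.values(), key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
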