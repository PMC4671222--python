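"""Synthetic benchmark generation: indel-mutated genomes, paired reads,
and an internal soft-clip-emitting read mapper.

The generator reproduces the benchmark design used throughout this
package's evaluation: the reference is divided into 1-kb bins, a random
subset of bins receives exactly one indel each (first half deletions,
second half insertions, sizes spanning 1 bp to 1 kb evenly), and
wgsim-style paired-end reads are sampled from the mutated genome with
insert size 500 +- 50, a 2% per-base sequencing error rate and a 0.1%
haplotype point-mutation rate, with no simulated indel errors.

``emulate_mapper`` plays the role of the upstream gapped short-read
aligner: seed-and-extend alignment with affine gap scoring in which any
single gap longer than ``max_indel_frac`` of the read length (20% by
default) is converted to a soft clip of the shorter-anchored side --
mirroring how BWT-based aligners handle indels beyond their gap-extension
reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from Bio import Align

from .alignment_core import AlignedRead, CigarString, normalize_ops, revcomp
from .realigner import ReferenceIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q_GOOD = 30 + 33  # '?'
_Q_ERR = 15 + 33   # '0'


@dataclass(frozen=True)
class SimulationConfig:
    bin_size: int = 1000
    n_del: int = 1000
    n_ins: int = 1000
    size_min: int = 1
    size_max: int = 1000
    read_len: int = 100
    coverage: float = 50.0
    insert_mean: int = 500
    insert_sd: int = 50
    base_error: float = 0.02
    mut_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_max > self.bin_size:
            raise ValueError("size_max must not exceed bin_size")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    start: int  # 0-based first affected reference base
    type: str  # "DEL" or "INS"
    size: int
    inserted_seq: str = ""

    @property
    def end(self) -> int:
        """0-based half-open end on the original reference."""
        return self.start + (self.size if self.type == "DEL" else 0)


def random_reference(length: int, seed: int, name: str = "sim_ref") -> dict[str, str]:
    """Uniform-ACGT synthetic reference chromosome."""
    rng = np.random.default_rng([seed, 0])
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return {name: seq}


def even_sizes(n: int, lo: int, hi: int) -> list[int]:
    """n indel sizes spanning [lo, hi] evenly (all integers when n covers the range)."""
    if n <= 0:
        return []
    if n == hi - lo + 1:
        return list(range(lo, hi + 1))
    if n == 1:
        return [hi]
    return [int(round(x)) for x in np.linspace(lo, hi, n)]


def _eligible_bins(reference: dict[str, str], bin_size: int) -> list[tuple[str, int]]:
    bins = []
    for chrom, seq in reference.items():
        for b in range(len(seq) // bin_size):
            if "N" not in seq[b * bin_size : (b + 1) * bin_size]:
                bins.append((chrom, b))
    return bins


def place_indels(
    reference: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Place non-overlapping indels in randomly selected bins.

    Returns the mutated genome and the truth set (original-reference
    coordinates, sorted).  The first half of the selected bins receive
    deletions, the second half insertions, one event per bin, sizes
    spanning ``[size_min, size_max]`` evenly within each class.
    """
    rng = np.random.default_rng([config.seed, 1])
    bins = _eligible_bins(reference, config.bin_size)
    need = config.n_del + config.n_ins
    if len(bins) < need:
        raise ValueError(
            f"need {need} eligible {config.bin_size}-bp bins, only {len(bins)} available"
        )
    chosen_idx = rng.choice(len(bins), size=need, replace=False)
    chosen = [bins[i] for i in chosen_idx]
    del_sizes = even_sizes(config.n_del, config.size_min, config.size_max)
    ins_sizes = even_sizes(config.n_ins, config.size_min, config.size_max)

    truth: list[TruthRecord] = []
    for (chrom, b), size in zip(chosen[: config.n_del], del_sizes):
        lo = max(b * config.bin_size, 1)  # keep a left anchor base available
        hi = (b + 1) * config.bin_size - size
        start = int(rng.integers(lo, max(hi, lo) + 1))
        truth.append(TruthRecord(chrom=chrom, start=start, type="DEL", size=size))
    for (chrom, b), size in zip(chosen[config.n_del :], ins_sizes):
        lo = max(b * config.bin_size, 1)
        hi = (b + 1) * config.bin_size - 1
        start = int(rng.integers(lo, hi + 1))
        ins = rng.choice(_BASES, size=size).tobytes().decode()
        truth.append(
            TruthRecord(chrom=chrom, start=start, type="INS", size=size, inserted_seq=ins)
        )
    truth.sort(key=lambda t: (t.chrom, t.start))

    mutated: dict[str, str] = {}
    for chrom, seq in reference.items():
        events = [t for t in truth if t.chrom == chrom]
        pieces: list[str] = []
        cursor = 0
        for ev in events:
            pieces.append(seq[cursor : ev.start])
            if ev.type == "DEL":
                cursor = ev.start + ev.size
            else:
                pieces.append(ev.inserted_seq)
                cursor = ev.start
        pieces.append(seq[cursor:])
        mutated[chrom] = "".join(pieces)
    return mutated, truth


def truth_to_calls(truth: Sequence[TruthRecord], reference: dict[str, str]):
    """Convert truth records to VCF-style :class:`IndelCall` objects."""
    from .alignment_core import IndelCall

    calls = []
    for t in truth:
        seq = reference[t.chrom]
        anchor = t.start - 1
        if anchor < 0:
            raise ValueError(f"truth event at {t.chrom}:{t.start} has no anchor base")
        if t.type == "DEL":
            ref = seq[anchor : anchor + t.size + 1]
            alt = seq[anchor]
        else:
            ref = seq[anchor]
            alt = ref + t.inserted_seq
        calls.append(
            IndelCall(
                chrom=t.chrom, pos=anchor + 1, ref=ref, alt=alt, svtype=t.type,
                size=t.size, support=1, depth=1, source="reads",
            )
        )
    return calls


def apply_point_mutations(genome: dict[str, str], rate: float, rng) -> dict[str, str]:
    """Substitute bases i.i.d. at the given rate (haplotype SNPs, no indels)."""
    if rate <= 0:
        return dict(genome)
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(arr.size) < rate)[0]
        if hit.size:
            shift = rng.integers(1, 4, size=hit.size)
            code = np.zeros(256, dtype=np.int8)
            for i, b in enumerate(b"ACGT"):
                code[b] = i
            cur = code[arr[hit]]
            arr[hit] = _BASES[(cur + shift) % 4]
        out[chrom] = arr.tobytes().decode()
    return out


def simulate_reads(
    genome: dict[str, str], config: SimulationConfig
) -> tuple[list[tuple[str, str, bytes]], list[tuple[str, str, bytes]]]:
    """wgsim-style paired reads: ``(read1s, read2s)`` as (name, seq, qual).

    Pair count is ceil(coverage * genome_len / (2 * read_len)); fragment
    lengths are Normal(insert_mean, insert_sd) truncated below at twice the
    read length.  Read 1 is the forward prefix of the fragment, read 2 the
    reverse complement of its suffix.  Base qualities are Q30, with
    sequencing-error positions marked Q15.
    """
    rng = np.random.default_rng([config.seed, 2])
    hap = apply_point_mutations(genome, config.mut_rate, rng)
    L = config.read_len
    reads1: list[tuple[str, str, bytes]] = []
    reads2: list[tuple[str, str, bytes]] = []
    serial = 0
    for chrom, seq in hap.items():
        glen = len(seq)
        n_pairs = math.ceil(config.coverage * glen / (2 * L))
        frags = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
        frags = np.clip(np.rint(frags), 2 * L, glen).astype(np.int64)
        starts = rng.integers(0, glen - frags + 1)
        nerr1 = rng.binomial(L, config.base_error, size=n_pairs)
        nerr2 = rng.binomial(L, config.base_error, size=n_pairs)
        for i in range(n_pairs):
            start = int(starts[i])
            end = start + int(frags[i])
            serial += 1
            name = f"{chrom}_{start}_{end}_{serial}"
            s1 = seq[start : start + L]
            s2 = revcomp(seq[end - L : end])
            reads1.append((name,) + _sequencing_errors(s1, int(nerr1[i]), rng))
            reads2.append((name,) + _sequencing_errors(s2, int(nerr2[i]), rng))
    return reads1, reads2


def _sequencing_errors(seq: str, n_err: int, rng) -> tuple[str, bytes]:
    qual = bytearray([_Q_GOOD]) * len(seq)
    if n_err == 0:
        return seq, bytes(qual)
    arr = bytearray(seq.encode())
    pos = rng.integers(0, len(seq), size=n_err)
    shift = rng.integers(1, 4, size=n_err)
    for p, s in zip(pos, shift):
        cur = b"ACGT".find(arr[p])
        if cur >= 0:
            arr[p] = _BASES[(cur + s) % 4]
        qual[p] = _Q_ERR
    return arr.decode(), bytes(qual)


# ---------------------------------------------------------------------------
# Internal soft-clip-emitting mapper


def _make_affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -4
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    aligner.end_deletion_score = 0.0  # read aligns to an infix of the window
    return aligner


def _parse_edlib_cigar(text: str) -> list[tuple[int, str]]:
    ops = []
    n = 0
    for ch in text:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            ops.append((n, ch))
            n = 0
    return ops


def _score_trim(ops: list[tuple[int, str]]) -> tuple[int, int, int, int]:
    """Column-score trimming of noisy alignment ends.

    Walks aligned columns with +1/match, -4/mismatch, -6-1/gap scoring from
    each end and returns (q_trim_left, t_trim_left, q_trim_right,
    t_trim_right): the query/target bases to drop so the alignment starts
    and ends at its score maxima.
    """
    cols: list[tuple[str, int]] = [(op, ln) for ln, op in ops]

    def one_side(seq_ops):
        score = best = 0.0
        q = t = 0
        best_q = best_t = 0
        for op, ln in seq_ops:
            if op in "=M":
                for _ in range(ln):
                    score += 1
                    q += 1
                    t += 1
                    if score > best:
                        best, best_q, best_t = score, q, t
            elif op == "X":
                score -= 4 * ln
                q += ln
                t += ln
            elif op == "I":
                score -= 5 + ln
                q += ln
            elif op == "D":
                score -= 5 + ln
                t += ln
        # drop everything before the best prefix from this side's view
        return q - best_q, t - best_t

    qr, tr = one_side(cols)
    ql, tl = one_side(cols[::-1])
    return ql, tl, qr, tr


def _ops_cut(ops: list[tuple[int, str]], q_left: int, q_right: int) -> tuple[list[tuple[int, str]], int]:
    """Clip q_left/q_right query bases off the ends; returns (ops, t_offset)."""
    t_off = 0
    remaining = list(ops)
    need = q_left
    while remaining and need > 0:
        ln, op = remaining[0]
        if op in "=XMI":
            take = min(ln, need)
            need -= take
            if op in "=XM":
                t_off += take
            if take < ln:
                remaining[0] = (ln - take, op)
                break
            remaining.pop(0)
        else:  # D consumed entirely while trimming
            t_off += ln
            remaining.pop(0)
    # drop gap runs left dangling at the new start
    while remaining and remaining[0][1] == "D":
        t_off += remaining[0][0]
        remaining.pop(0)
    need = q_right
    while remaining and need > 0:
        ln, op = remaining[-1]
        if op in "=XMI":
            take = min(ln, need)
            need -= take
            if take < ln:
                remaining[-1] = (ln - take, op)
                break
            remaining.pop()
        else:
            remaining.pop()
    while remaining and remaining[-1][1] == "D":
        remaining.pop()
    if q_left:
        remaining = [(q_left, "S")] + remaining
    if q_right:
        remaining = remaining + [(q_right, "S")]
    return remaining, t_off


def _trim_noise(ops: list[tuple[int, str]]) -> Optional[tuple[list[tuple[int, str]], int]]:
    """Score-trim noisy terminal columns of the aligned core (S ends preserved).

    Returns (ops, extra target offset) or None when nothing alignable
    remains.
    """
    lead = ops[0][0] if ops and ops[0][1] == "S" else 0
    tail = ops[-1][0] if ops and ops[-1][1] == "S" else 0
    core = ops[1 if lead else 0 : len(ops) - (1 if tail else 0)]
    ql, _, qr, _ = _score_trim(core)
    if ql == 0 and qr == 0:
        return ops, 0
    core_q = sum(l for l, o in core if o in "=XMI")
    if ql + qr >= core_q:
        return None
    core, t_off = _ops_cut(core, ql, qr)
    merged: list[tuple[int, str]] = []
    if lead + ql:
        merged.append((lead + ql, "S"))
    merged += [o for o in core if o[1] != "S"]
    if tail + qr:
        merged.append((tail + qr, "S"))
    return merged, t_off


def _big_gap_to_clip(ops: list[tuple[int, str]], max_gap: int) -> tuple[list[tuple[int, str]], int]:
    """Convert any internal gap run longer than max_gap into a soft clip.

    The side of the gap carrying fewer query bases is clipped; returns the
    new ops and the additional target offset if the left side was clipped.
    """
    t_off_total = 0
    changed = True
    while changed:
        changed = False
        q_before = 0
        for idx, (ln, op) in enumerate(ops):
            if op in ("I", "D") and ln > max_gap and 0 < idx < len(ops) - 1:
                q_after = sum(l for l, o in ops[idx + 1 :] if o in "=XMIS")
                if q_before >= q_after:
                    clip = q_after + (ln if op == "I" else 0)
                    ops = ops[:idx] + ([(clip, "S")] if clip else [])
                else:
                    clip = q_before + (ln if op == "I" else 0)
                    t_off = sum(l for l, o in ops[: idx + 1] if o in "=XMD")
                    t_off_total += t_off
                    ops = ([(clip, "S")] if clip else []) + ops[idx + 1 :]
                changed = True
                break
            if op in "=XMIS":
                q_before += ln
        if not changed:
            break
    return ops, t_off_total


def _finalize_ops(ops: list[tuple[int, str]]) -> Optional[CigarString]:
    sam_ops = []
    for ln, op in ops:
        if ln <= 0:
            continue
        sam_ops.append((ln, "M" if op in "=X" else op))
    if not sam_ops or all(op != "M" for _, op in sam_ops):
        return None
    return CigarString(normalize_ops(sam_ops))


class MapperEmulator:
    """Seed-and-extend read mapper with BWA-like soft-clipping behaviour."""

    def __init__(
        self,
        reference: dict[str, str],
        index: Optional[ReferenceIndex] = None,
        max_indel_frac: float = 0.20,
        min_anchor: int = 25,
    ):
        self.reference = reference
        self.index = index if index is not None else ReferenceIndex(reference)
        self.max_indel_frac = max_indel_frac
        self.min_anchor = min_anchor
        self.affine = _make_affine_aligner()

    # -- candidate location ------------------------------------------------
    def _probe(self, seq: str):
        index = self.index
        k = index.k
        L = len(seq)
        if L < k:
            return None
        if L <= 200:
            span = L - k
            offsets = sorted({0, span // 4, span // 2, 3 * span // 4, span})
        else:
            offsets = list(range(0, L - k + 1, 50))
        candidates = []  # (votes, strand, diag_global)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            votes: dict[int, int] = {}
            for q in offsets:
                for t in index.lookup(s[q : q + k]):
                    votes[t - q] = votes.get(t - q, 0) + 1
            for diag, v in votes.items():
                candidates.append((v, strand, diag))
        if not candidates:
            return None
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        v1, strand, diag = candidates[0]
        # uniqueness: strongest competitor at a distant locus or other strand
        v2 = 0
        for v, s2, d2 in candidates[1:]:
            if s2 != strand or abs(d2 - diag) > 1000:
                v2 = v
                break
        mapq = 60 if v2 == 0 else (20 if v2 < v1 else 0)
        return strand, diag, mapq

    # -- alignment ---------------------------------------------------------
    def _align_window(self, seq: str, chrom: str, tstart: int):
        """Align read to window around tstart; returns (ops, local pos) or None."""
        ref = self.reference[chrom]
        L = len(seq)
        pad = int(self.max_indel_frac * L) + 12
        w0 = max(0, tstart - pad)
        w1 = min(len(ref), tstart + L + pad)
        window = ref[w0:w1]
        if not window:
            return None
        res = edlib.align(seq, window, mode="HW", task="path")
        ops = _parse_edlib_cigar(res["cigar"] or "")
        loc = res["locations"][0]
        has_gap = any(op in "ID" for _, op in ops)
        if not has_gap:
            ql, _, qr, _ = _score_trim(ops)
            if ql <= 4 and qr <= 4:
                return ops, w0 + loc[0]
        # indel-bearing or messy read: redo with affine scoring
        return self._align_affine(seq, window, w0)

    def _align_affine(self, seq: str, window: str, w0: int):
        try:
            aln = self.affine.align(window, seq)[0]
        except (IndexError, OverflowError, MemoryError):
            return None
        t_blocks, q_blocks = aln.aligned
        if len(q_blocks) == 0:
            return None
        ops: list[tuple[int, str]] = []
        lead = int(q_blocks[0][0])
        if lead:
            ops.append((lead, "S"))
        prev_q = prev_t = None
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            t0, t1, q0, q1 = int(t0), int(t1), int(q0), int(q1)
            if prev_q is not None:
                if q0 > prev_q:
                    ops.append((q0 - prev_q, "I"))
                if t0 > prev_t:
                    ops.append((t0 - prev_t, "D"))
            # split matched segment into =/X columns
            run = 0
            run_op = None
            for x in range(q1 - q0):
                op = "=" if seq[q0 + x] == window[t0 + x] else "X"
                if op == run_op:
                    run += 1
                else:
                    if run:
                        ops.append((run, run_op))
                    run, run_op = 1, op
            if run:
                ops.append((run, run_op))
            prev_q, prev_t = q1, t1
        tail = len(seq) - prev_q
        if tail:
            ops.append((tail, "S"))
        pos = int(t_blocks[0][0])
        return ops, w0 + pos

    # -- public ------------------------------------------------------------
    def map_read(self, name: str, seq: str, qual: bytes, **flags) -> AlignedRead:
        probe = self._probe(seq)
        if probe is None:
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        strand, diag, mapq = probe
        oriented = seq if strand == "+" else revcomp(seq)
        chrom, local_diag = self.index.locate(max(diag, 0)) if diag >= 0 else (None, None)
        if chrom is None:
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        aligned = self._align_window(oriented, chrom, local_diag)
        if aligned is None:
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        ops, pos = aligned
        max_gap = max(1, int(self.max_indel_frac * len(seq)))
        ops, t_off = _big_gap_to_clip(ops, max_gap)
        pos += t_off
        trimmed = _trim_noise(ops)
        if trimmed is None:
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        ops, t_off = trimmed
        pos += t_off
        cigar = _finalize_ops(ops)
        if cigar is None or cigar.query_length != len(seq):
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        matched = sum(ln for ln, op in cigar if op == "M")
        if matched < min(self.min_anchor, len(seq)):
            return AlignedRead(name=name, seq=seq, quals=qual, is_unmapped=True, **flags)
        if strand == "-":
            seq = revcomp(seq)
            qual = qual[::-1]
        return AlignedRead(
            name=name, seq=seq, quals=qual, chrom=chrom, pos=pos, mapq=mapq,
            cigar=cigar, is_unmapped=False, is_reverse=(strand == "-"), **flags,
        )


def emulate_mapper(
    reads: Iterable[tuple[str, str, bytes]],
    reference: dict[str, str],
    index: Optional[ReferenceIndex] = None,
    max_indel_frac: float = 0.20,
) -> list[AlignedRead]:
    """Map single-end reads (name, seq, qual) against the reference."""
    mapper = MapperEmulator(reference, index=index, max_indel_frac=max_indel_frac)
    return [mapper.map_read(name, seq, qual) for name, seq, qual in reads]


def emulate_mapper_paired(
    reads1: Sequence[tuple[str, str, bytes]],
    reads2: Sequence[tuple[str, str, bytes]],
    reference: dict[str, str],
    index: Optional[ReferenceIndex] = None,
    max_indel_frac: float = 0.20,
) -> list[AlignedRead]:
    """Map read pairs; mates share a name and carry read1/read2 flags."""
    mapper = MapperEmulator(reference, index=index, max_indel_frac=max_indel_frac)
    out = []
    for (n1, s1, q1), (n2, s2, q2) in zip(reads1, reads2):
        out.append(mapper.map_read(n1, s1, q1, is_paired=True, is_read1=True))
        out.append(mapper.map_read(n2, s2, q2, is_paired=True, is_read2=True))
    return out
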