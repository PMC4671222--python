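"""Large-gap realignment of breakpoint-supported soft-clipped reads.

The engine is a seed-chain-join aligner: exact seed words are located in a
k-mer index of the reference, seeds sharing a diagonal are merged into
gapless segments, and segments are chained across large target gaps
(deletions, up to ``max_target_gap``) or query gaps (insertions).  The
junction between two chained segments is placed at the split point that
maximizes the number of matching columns, with the leftmost split winning
ties, so that every read crossing the same junction reports the same indel.

Accepted alignments are represented as block-structured :class:`PslHit`
objects, scored like the UCSC web BLAT (matches - mismatches - query gap
openings - target gap openings) and accepted only when the top-ranked hit
has score > ``min_score`` and identity > ``min_identity``.  Accepted hits
replace the original alignment record after conversion of the block
structure to a SAM CIGAR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

from .alignment_core import AlignedRead, CigarString, parse_cigar, revcomp


@dataclass(frozen=True)
class PslHit:
    """Block-structured gapped alignment of one query against the reference."""

    strand: str  # "+" or "-" (query orientation)
    q_start: int
    q_end: int
    t_name: str
    blocks: tuple[tuple[int, int, int], ...]  # (q_block_start, t_block_start, len)
    matches: int
    mismatches: int
    q_gap_count: int
    t_gap_count: int

    def __post_init__(self) -> None:
        prev_q = prev_t = -1
        total = 0
        for q, t, ln in self.blocks:
            if ln <= 0 or q < prev_q or t < prev_t:
                raise ValueError("blocks must be strictly increasing with positive length")
            prev_q, prev_t = q + ln, t + ln
            total += ln
        if total != self.matches + self.mismatches:
            raise ValueError("block lengths must sum to matches + mismatches")
        if self.q_end - self.q_start < total:
            raise ValueError("query span smaller than total block length")

    @property
    def t_start(self) -> int:
        return self.blocks[0][1]

    @property
    def t_end(self) -> int:
        q, t, ln = self.blocks[-1]
        return t + ln


@dataclass(frozen=True)
class RealignerParams:
    min_score: int = 30
    min_identity: float = 0.90
    seed_k: int = 16
    max_target_gap: int = 100_000
    region_window: int = 50_000
    max_seed_hits: int = 16
    chain_gap_penalty: int = 8
    xdrop: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


class ReferenceIndex:
    """Exact k-mer index over a reference genome (concatenated coordinates)."""

    def __init__(self, reference: dict[str, str], k: int = 16, max_hits: int = 16):
        self.k = k
        self.max_hits = max_hits
        self.names = list(reference)
        self.offsets: dict[str, int] = {}
        self.bounds: list[tuple[int, int, str]] = []
        off = 0
        for name in self.names:
            self.offsets[name] = off
            length = len(reference[name])
            self.bounds.append((off, off + length, name))
            off += length
        self.total = off
        self.seqs = reference
        index: dict[str, list[int] | None] = {}
        for name in self.names:
            seq = reference[name]
            base = self.offsets[name]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                cur = index.get(kmer)
                if cur is None:
                    if kmer in index:  # over-represented, already dropped
                        continue
                    index[kmer] = [base + i]
                elif len(cur) >= max_hits:
                    index[kmer] = None
                else:
                    cur.append(base + i)
        self.index = index

    def lookup(self, kmer: str) -> list[int]:
        hits = self.index.get(kmer)
        return hits if hits else []

    def locate(self, gpos: int) -> tuple[str, int]:
        for start, end, name in self.bounds:
            if start <= gpos < end:
                return name, gpos - start
        raise IndexError(f"global position {gpos} outside reference")


def blat_score(hit: PslHit) -> int:
    """Web-BLAT style score: matches - mismatches - gap openings."""
    return hit.matches - hit.mismatches - hit.q_gap_count - hit.t_gap_count


def identity(hit: PslHit) -> float:
    """Fraction of matching columns among aligned (non-gap) columns."""
    denom = hit.matches + hit.mismatches
    if denom == 0:
        raise ValueError("identity undefined for an empty alignment")
    return hit.matches / denom


def accept_hit(hits: Sequence[PslHit], params: RealignerParams) -> Optional[PslHit]:
    """Return the top-ranked hit iff it clears the score and identity bars."""
    if not hits:
        return None
    top = hits[0]
    if blat_score(top) > params.min_score and identity(top) > params.min_identity:
        return top
    return None


# ---------------------------------------------------------------------------
# Seed - chain - join

def _collect_segments(query, index, hint, params):
    """Seeds grouped by (chrom, diagonal) into gapless candidate segments."""
    k = index.k
    if len(query) < k:
        return []
    step = 1 if len(query) <= 256 else 2
    lo = hi = None
    hint_chrom = None
    if hint is not None:
        hint_chrom, center = hint
        base = index.offsets.get(hint_chrom)
        if base is None:
            return []
        lo = base + max(0, center - params.region_window)
        hi = base + center + params.region_window
    diag_hits: dict[int, list[int]] = {}
    for qpos in range(0, len(query) - k + 1, step):
        for t in index.lookup(query[qpos : qpos + k]):
            if lo is not None and not (lo <= t <= hi):
                continue
            diag_hits.setdefault(t - qpos, []).append(qpos)
    segments = []
    for diag, qlist in diag_hits.items():
        qlist.sort()
        # split runs with large unseeded interior into separate segments
        run_start = prev = qlist[0]
        covered = k
        for qpos in qlist[1:]:
            if qpos - prev > 3 * k:
                segments.append((diag, run_start, prev + k, covered))
                run_start, covered = qpos, 0
            covered += min(k, qpos - prev) if qpos > prev else 0
            prev = qpos
        segments.append((diag, run_start, prev + k, covered))
    # strongest segments first; cap the number considered
    segments.sort(key=lambda s: (-s[3], s[0], s[1]))
    return segments[:24]


def _chain_segments(segments, index, qlen, params):
    """Best-scoring increasing chains of diagonal segments (simple DP)."""
    # order by query start for DP
    segs = sorted(segments, key=lambda s: (s[1], s[0]))
    n = len(segs)
    best = [s[3] for s in segs]
    back = [-1] * n
    for j in range(n):
        dj, qs_j, qe_j, cov_j = segs[j]
        for i in range(j):
            di, qs_i, qe_i, cov_i = segs[i]
            if di == dj:
                continue
            # target must advance; same-chromosome check happens later
            if qs_j + dj <= qs_i + di:
                continue
            if qs_j < qs_i + 1:
                continue
            gap = abs(dj - di)
            if dj > di and gap > params.max_target_gap:
                continue
            if dj < di and gap > qlen:
                continue
            cand = best[i] + cov_j - params.chain_gap_penalty
            if cand > best[j]:
                best[j] = cand
                back[j] = i
    chains = []
    used: set[int] = set()
    for j in sorted(range(n), key=lambda j: -best[j]):
        if j in used:
            continue
        chain = []
        i = j
        while i != -1:
            chain.append(segs[i])
            used.add(i)
            i = back[i]
        chain.reverse()
        chains.append((best[j], chain))
    return chains[:6]


def _extend_left(query, ref, q, t, xdrop):
    """Greedy X-drop extension towards lower coordinates; returns new (q, t)."""
    best_q, best_t = q, t
    score = best = 0
    while q > 0 and t > 0:
        q -= 1
        t -= 1
        score += 1 if query[q] == ref[t] else -3
        if score > best:
            best, best_q, best_t = score, q, t
        elif best - score > xdrop:
            break
    return best_q, best_t


def _extend_right(query, ref, q, t, xdrop):
    best_q, best_t = q, t
    score = best = 0
    qlen, tlen = len(query), len(ref)
    while q < qlen and t < tlen:
        score += 1 if query[q] == ref[t] else -3
        q += 1
        t += 1
        if score > best:
            best, best_q, best_t = score, q, t
        elif best - score > xdrop:
            break
    return best_q, best_t


def _refine_chain(query, chrom, ref, chain_local, params):
    """Turn a chain of (diag, qs, qe) segments into exact, split-optimized blocks."""
    blocks: list[list[int]] = []  # [q_start, t_start, length]
    chain = chain_local
    # outer extensions
    d0, qs0, qe0 = chain[0]
    qs0, ts0 = _extend_left(query, ref, qs0, qs0 + d0, params.xdrop)
    dl, qsl, qel = chain[-1]
    qel, tel = _extend_right(query, ref, qel, qel + dl, params.xdrop)
    spans = [[d, qs, qe] for d, qs, qe in chain]
    spans[0][1] = qs0
    spans[-1][2] = qel

    # resolve junction split points
    tlen = len(ref)
    qlen = len(query)

    def _m(x: int, d: int) -> int:
        t = x + d
        return 1 if 0 <= x < qlen and 0 <= t < tlen and query[x] == ref[t] else 0

    cuts: list[tuple[int, int]] = []  # (q_end_of_left_block, q_start_of_right_block)
    for (d1, qs1, qe1), (d2, qs2, qe2) in zip(spans, spans[1:]):
        if d2 > d1:  # deletion: query contiguous, target jumps
            lo, hi = max(qs1 + 1, 1), qe2 - 1
            best_q = max(lo, min(qe1, hi)) if hi <= lo else None
            best_score = None
            pre = 0
            m2 = [_m(x, d2) for x in range(lo, max(hi, lo))]
            suf = sum(m2)
            for q in range(lo, hi):
                sc = pre + suf
                if best_score is None or sc > best_score:
                    best_score, best_q = sc, q
                pre += _m(q, d1)
                suf -= m2[q - lo]
            cuts.append((best_q, best_q))
        else:  # insertion: target contiguous, query jumps by s
            s = d1 - d2
            lo = qs1 + 1
            hi = qe2 - 1 - s
            best_q = max(lo, min(qe1, hi if hi > lo else lo)) if hi <= lo else None
            best_score = None
            pre = 0
            m2 = [_m(x + s, d2) for x in range(lo, max(hi, lo))]
            suf = sum(m2)
            for q in range(lo, hi):
                sc = pre + suf
                if best_score is None or sc > best_score:
                    best_score, best_q = sc, q
                pre += _m(q, d1)
                suf -= m2[q - lo]
            cuts.append((best_q, best_q + s))

    # assemble blocks from spans and cuts
    for i, (d, qs, qe) in enumerate(spans):
        q_from = qs if i == 0 else cuts[i - 1][1]
        q_to = qe if i == len(spans) - 1 else cuts[i][0]
        if q_to <= q_from:
            continue
        blocks.append([q_from, q_from + d, q_to - q_from])

    if not blocks:
        return None
    # trim outer mismatching columns
    while blocks:
        q, t, ln = blocks[0]
        while ln > 0 and query[q] != ref[t]:
            q += 1
            t += 1
            ln -= 1
        if ln > 0:
            blocks[0] = [q, t, ln]
            break
        blocks.pop(0)
    while blocks:
        q, t, ln = blocks[-1]
        while ln > 0 and query[q + ln - 1] != ref[t + ln - 1]:
            ln -= 1
        if ln > 0:
            blocks[-1][2] = ln
            break
        blocks.pop()
    if not blocks:
        return None

    matches = mismatches = 0
    q_gaps = t_gaps = 0
    cleaned: list[tuple[int, int, int]] = []
    for q, t, ln in blocks:
        if cleaned:
            pq, pt, pl = cleaned[-1]
            if q < pq + pl or t < pt + pl:
                return None  # inconsistent chain geometry
            if q == pq + pl and t == pt + pl:
                cleaned[-1] = (pq, pt, pl + ln)
            else:
                if q > pq + pl:
                    q_gaps += 1
                if t > pt + pl:
                    t_gaps += 1
                cleaned.append((q, t, ln))
        else:
            cleaned.append((q, t, ln))
    for q, t, ln in cleaned:
        m = sum(1 for x in range(ln) if query[q + x] == ref[t + x])
        matches += m
        mismatches += ln - m
    return cleaned, matches, mismatches, q_gaps, t_gaps


def gapped_align(
    query: str,
    reference: dict[str, str],
    index: ReferenceIndex,
    region_hint: Optional[tuple[str, int]] = None,
    params: RealignerParams = RealignerParams(),
) -> list[PslHit]:
    """Align a query against the reference; ranked hits, best first.

    ``region_hint`` restricts the seed search to +-``region_window`` of a
    (chrom, position) locus; pass ``None`` for a genome-wide search.
    """
    hits: list[PslHit] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        segments = _collect_segments(q, index, region_hint, params)
        if not segments:
            continue
        # localize to per-chromosome coordinates, grouping by chromosome
        by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
        for diag, qs, qe, cov in segments:
            chrom, local = index.locate(diag + qs)
            local_diag = local - qs
            if qe + local_diag > len(reference[chrom]):
                continue
            by_chrom.setdefault(chrom, []).append((local_diag, qs, qe, cov))
        for chrom, segs in by_chrom.items():
            ref = reference[chrom]
            for score, chain in _chain_segments(segs, index, len(q), params):
                refined = _refine_chain(q, chrom, ref, [(d, a, b) for d, a, b, _ in chain], params)
                if refined is None:
                    continue
                blocks, matches, mismatches, q_gaps, t_gaps = refined
                hits.append(
                    PslHit(
                        strand=strand,
                        q_start=blocks[0][0],
                        q_end=blocks[-1][0] + blocks[-1][2],
                        t_name=chrom,
                        blocks=tuple(blocks),
                        matches=matches,
                        mismatches=mismatches,
                        q_gap_count=q_gaps,
                        t_gap_count=t_gaps,
                    )
                )
    hits.sort(key=lambda h: (-blat_score(h), h.t_name, h.t_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# PSL -> SAM

def psl_to_cigar(hit: PslHit, read_len: int) -> tuple[int, CigarString]:
    """Convert a plus-strand block alignment to (0-based pos, CIGAR).

    Leading/trailing unaligned query bases become soft clips; a query gap
    between blocks becomes I, a target gap D (a simultaneous gap emits I
    then D).
    """
    ops: list[tuple[int, str]] = []
    if hit.q_start > 0:
        ops.append((hit.q_start, "S"))
    prev_q = prev_t = None
    for q, t, ln in hit.blocks:
        if prev_q is not None:
            q_gap = q - prev_q
            t_gap = t - prev_t
            if q_gap < 0 or t_gap < 0:
                raise ValueError("blocks overlap; inconsistent PSL hit")
            if q_gap:
                ops.append((q_gap, "I"))
            if t_gap:
                ops.append((t_gap, "D"))
        ops.append((ln, "M"))
        prev_q, prev_t = q + ln, t + ln
    tail = read_len - hit.q_end
    if tail < 0:
        raise ValueError("q_end exceeds read length")
    if tail:
        ops.append((tail, "S"))
    return hit.t_start, CigarString(tuple(ops))


def replace_alignment(read: AlignedRead, accepted: PslHit) -> AlignedRead:
    """Swap the read's alignment for an accepted realignment hit.

    Sequence, qualities, name and pairing flags are preserved (reverse-
    complemented if the hit is on the opposite strand); the original
    position and CIGAR are kept in an ``OA`` provenance tag.  If the
    converted CIGAR fails the query-consumption check the original record
    is returned unchanged and the failure is signalled by identity.
    """
    flip = (accepted.strand == "-")
    seq = revcomp(read.seq) if flip else read.seq
    quals = read.quals[::-1] if flip else read.quals
    pos, cigar = psl_to_cigar(accepted, len(seq))
    if cigar.query_length != len(seq):
        return read
    tags = dict(read.tags)
    orig = (
        f"{read.chrom},{(read.pos or 0) + 1},{'-' if read.is_reverse else '+'},{read.cigar}"
        if not read.is_unmapped
        else "*,0,+,*"
    )
    tags["OA"] = orig
    return dc_replace(
        read,
        seq=seq,
        quals=quals,
        chrom=accepted.t_name,
        pos=pos,
        cigar=cigar,
        mapq=max(read.mapq, 1),
        is_unmapped=False,
        is_reverse=read.is_reverse ^ flip,
        tags=tags,
    )


def write_realignment_report(report: "RealignmentReport", path) -> None:
    """TSV of accepted replacements: read, old and new locus/CIGAR, score, identity."""
    with open(path, "w") as fh:
        fh.write("read\told_chrom\told_pos\told_cigar\tnew_chrom\tnew_pos\t"
                 "new_cigar\tscore\tidentity\n")
        for row in report.rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class RealignmentReport:
    attempted: int = 0
    accepted: int = 0
    rejected: int = 0
    failed: int = 0
    rows: list[tuple] = None

    def __post_init__(self):
        if self.rows is None:
            self.rows = []


def realign_reads(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    index: ReferenceIndex,
    params: RealignerParams = RealignerParams(),
) -> tuple[dict[int, AlignedRead], RealignmentReport]:
    """Realign each read; returns replacements keyed by ``id(read)`` plus a report.

    Keys are object identities because paired-end mates legitimately share
    a read name.  The search is first restricted to the neighbourhood of
    the original locus and falls back to a genome-wide search when nothing
    is accepted.
    """
    report = RealignmentReport()
    replaced: dict[int, AlignedRead] = {}
    for read in reads:
        report.attempted += 1
        hint = None if read.is_unmapped else (read.chrom, read.pos)
        hits = gapped_align(read.seq, reference, index, hint, params)
        top = accept_hit(hits, params)
        if top is None and hint is not None:
            hits = gapped_align(read.seq, reference, index, None, params)
            top = accept_hit(hits, params)
        if top is None:
            report.rejected += 1
            continue
        new = replace_alignment(read, top)
        if new is read:
            report.failed += 1
            continue
        report.accepted += 1
        report.rows.append(
            (read.name, read.chrom, read.pos, str(read.cigar), new.chrom, new.pos,
             str(new.cigar), blat_score(top), round(identity(top), 4))
        )
        replaced[id(read)] = new
    return replaced, report
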