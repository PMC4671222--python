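"""Greedy k-mer contig assembly of breakpoint-supported and unmapped reads.

The assembler is the classic greedy-extension scheme: count canonical
k-mers over all input reads, seed a contig at the most abundant unused
k-mer, and extend in both directions one base at a time, always taking the
most abundant (k-1)-overlap extension (ties broken by the alphabetically
smallest base).  Extension stops when no unused extension with count >=
``min_kmer_count`` exists.  Contigs shorter than ``min_contig_len`` -- by
default one base longer than the read length, so that a contig can expose
an indel no read could span -- are discarded.

Assembled contigs are pushed through the same cascade as reads: initial
mapping, soft-clip triage with the binomial breakpoint test (degenerate at
contig depth, so effectively a pass-through for singleton contigs), and
large-gap realignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .alignment_core import AlignedRead, revcomp
from .softclip_breakpoint import (
    DepthProfile,
    SoftClipCriteria,
    classify_read,
    ReadClass,
    find_breakpoint_clusters,
    cluster_member_reads,
)
from .realigner import RealignerParams, ReferenceIndex, realign_reads

logger = logging.getLogger(__name__)


@dataclass
class KmerTable:
    """Canonical-orientation k-mer occurrence counts."""

    k: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k must be >= 11")


@dataclass
class Contig:
    id: str
    seq: str
    n_reads_used: int
    mean_kmer_coverage: float


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_table(reads: Iterable[str], k: int = 25) -> KmerTable:
    """Count every k-length window of every read, strand-canonicalized.

    Reads shorter than k contribute nothing; k-mers containing N are
    skipped.
    """
    counts: dict[str, int] = {}
    for seq in reads:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        rc = revcomp(seq)
        L = len(seq)
        for i in range(n):
            fwd = seq[i : i + k]
            if "N" in fwd:
                continue
            rev = rc[L - k - i : L - i]
            kmer = fwd if fwd <= rev else rev
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerTable(k=k, counts=counts)


def _best_extension(core, counts, used, min_count, right: bool):
    """Highest-count unused extension of a (k-1)-mer core; None if exhausted."""
    best = None
    for base in "ACGT":
        kmer = core + base if right else base + core
        canon = canonical(kmer)
        if canon in used:
            continue
        cnt = counts.get(canon, 0)
        if cnt < min_count:
            continue
        if best is None or cnt > best[0]:
            best = (cnt, base, canon)
    return best


def inchworm_assemble(
    table: KmerTable,
    min_contig_len: int,
    min_kmer_count: int = 1,
) -> list[Contig]:
    """Greedy assembly of the k-mer table into contigs.

    Deterministic for a given k-mer multiset: seeds are taken in order of
    descending count (lexicographic tie-break) and extension ties go to the
    alphabetically smallest base.
    """
    k = table.k
    counts = table.counts
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    used: set[str] = set()
    contigs: list[Contig] = []
    for seed, seed_count in order:
        if seed in used or seed_count < min_kmer_count:
            continue
        used.add(seed)
        consumed = [seed_count]
        contig = seed
        # extend right
        while True:
            ext = _best_extension(contig[-(k - 1):], counts, used, min_kmer_count, right=True)
            if ext is None:
                break
            cnt, base, canon = ext
            contig += base
            used.add(canon)
            consumed.append(cnt)
        # extend left
        while True:
            ext = _best_extension(contig[: k - 1], counts, used, min_kmer_count, right=False)
            if ext is None:
                break
            cnt, base, canon = ext
            contig = base + contig
            used.add(canon)
            consumed.append(cnt)
        if len(contig) >= min_contig_len:
            contigs.append(
                Contig(
                    id="",  # assigned after deterministic ordering
                    seq=contig,
                    n_reads_used=0,
                    mean_kmer_coverage=sum(consumed) / len(consumed),
                )
            )
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    for i, contig in enumerate(contigs, start=1):
        contig.id = f"contig_{i}"
    return contigs


def attribute_reads(contigs: Sequence[Contig], reads: Iterable[str], k: int) -> None:
    """Fill ``n_reads_used``: reads sharing at least one k-mer with the contig."""
    kmer_to_contig: dict[str, int] = {}
    for idx, contig in enumerate(contigs):
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            kmer_to_contig.setdefault(canonical(seq[i : i + k]), idx)
    tallies = [0] * len(contigs)
    for seq in reads:
        hit: set[int] = set()
        for i in range(len(seq) - k + 1):
            idx = kmer_to_contig.get(canonical(seq[i : i + k]))
            if idx is not None:
                hit.add(idx)
        for idx in hit:
            tallies[idx] += 1
    for contig, n in zip(contigs, tallies):
        contig.n_reads_used = n


def assemble_and_map(
    clip_reads: Sequence[AlignedRead],
    unmapped_reads: Sequence[AlignedRead],
    reference: dict[str, str],
    read_len: int,
    index: Optional[ReferenceIndex] = None,
    k: int = 25,
    min_kmer_count: int = 1,
    min_contig_len: Optional[int] = None,
    mapper=None,
    criteria: SoftClipCriteria = SoftClipCriteria(),
    realigner_params: RealignerParams = RealignerParams(),
    het_factor: float = 0.1,
    alpha: float = 0.05,
) -> tuple[list[AlignedRead], list[Contig]]:
    """Assemble the selected reads and align contigs through the full cascade.

    ``mapper`` is the initial contig aligner, a callable with the signature
    of :func:`clipscan.simulator.emulate_mapper`; it is injected to avoid a
    circular import and defaults to that function.  Returns the final
    contig alignment records and the contigs themselves.
    """
    if min_contig_len is None:
        min_contig_len = read_len + 1
    if mapper is None:
        from .simulator import emulate_mapper as mapper  # late import

    sequences = [r.seq for r in clip_reads] + [r.seq for r in unmapped_reads]
    if not sequences:
        return [], []
    table = build_kmer_table(sequences, k=k)
    contigs = inchworm_assemble(table, min_contig_len=min_contig_len,
                                min_kmer_count=min_kmer_count)
    if not contigs:
        logger.info("assembly produced no contig of length >= %d", min_contig_len)
        return [], []
    attribute_reads(contigs, sequences, k)

    contig_reads = [
        (c.id, c.seq, b"I" * len(c.seq))  # constant Q40 placeholder qualities
        for c in contigs
    ]
    if index is None:
        index = ReferenceIndex(reference, k=realigner_params.seed_k)
    records = mapper(contig_reads, reference, index=index)
    mapped = [r for r in records if not r.is_unmapped]
    if not mapped:
        return [], contigs

    # contig-level soft-clip triage and breakpoint test
    lengths = {name: len(seq) for name, seq in reference.items()}
    depth = DepthProfile.from_reads(mapped, lengths)
    clipped = [r for r in mapped if classify_read(r, criteria) is ReadClass.HQ_SOFTCLIP]
    clusters = find_breakpoint_clusters(clipped, depth, q=het_factor, alpha=alpha)
    retained = cluster_member_reads(clusters, clipped)
    replaced, _report = realign_reads(retained, reference, index, realigner_params)

    final = [replaced.get(id(r), r) for r in mapped]
    for rec in final:
        rec.check_query_consumption()
    return final, contigs
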