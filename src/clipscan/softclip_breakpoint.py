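"""Soft-clip triage and binomial breakpoint evidence.

Reads are partitioned into three classes: high-quality soft-clipped reads,
unmapped reads and all other mapped reads.  Soft-clipped reads are then
grouped into per-position clusters and kept only when the number of clipped
reads k out of the n mapped reads covering the locus is improbably large
under a Binomial(n, q) noise model, where q is a small "heterogeneity
factor" absorbing clipping caused by sequencing error and alignment
ambiguity.  The evidence statistic is the binomial survival function

    P = sum_{i=k+1}^{n} C(n, i) q^i (1-q)^(n-i)

and a cluster is retained when P < alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .alignment_core import AlignedRead, clipped_fraction


class ReadClass(Enum):
    HQ_SOFTCLIP = "HQ_SOFTCLIP"
    UNMAPPED = "UNMAPPED"
    OTHER_MAPPED = "OTHER_MAPPED"


@dataclass(frozen=True)
class SoftClipCriteria:
    """Tiered quality filters defining a high-quality soft-clipped read."""

    min_mapq: int = 1
    min_clip_frac: float = 0.20
    min_base_quality: int = 20
    min_highq_frac: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_clip_frac <= 1) or not (0 < self.min_highq_frac <= 1):
            raise ValueError("proportions must lie in (0, 1]")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class BreakpointCluster:
    """Soft-clipped reads sharing one clip coordinate and clip side."""

    chrom: str
    position: int  # 0-based breakpoint coordinate of the clip
    side: str  # "L": clip precedes the alignment; "R": clip follows it
    k: int  # high-quality soft-clipped reads clipped here
    n: int  # mapped reads covering the locus
    q: float
    p_value: float
    member_reads: list[str] = field(default_factory=list)


def classify_read(read: AlignedRead, criteria: SoftClipCriteria) -> ReadClass:
    """Assign a read to exactly one of the three triage classes."""
    if read.is_unmapped:
        return ReadClass.UNMAPPED
    if read.cigar is None or read.cigar.clipped_length == 0:
        return ReadClass.OTHER_MAPPED
    if read.mapq < criteria.min_mapq:
        return ReadClass.OTHER_MAPPED
    if clipped_fraction(read) < criteria.min_clip_frac:
        return ReadClass.OTHER_MAPPED
    quals = read.quals
    thresh = criteria.min_base_quality + 33
    n_clip = hi = 0
    left = read.cigar.left_clip
    if left:
        n_clip += left
        hi += sum(1 for q in quals[:left] if q >= thresh)
    right = read.cigar.right_clip
    if right:
        n_clip += right
        hi += sum(1 for q in quals[len(quals) - right :] if q >= thresh)
    if n_clip == 0 or hi / n_clip < criteria.min_highq_frac:
        return ReadClass.OTHER_MAPPED
    return ReadClass.HQ_SOFTCLIP


def partition_reads(
    reads: Iterable[AlignedRead], criteria: SoftClipCriteria
) -> dict[ReadClass, list[AlignedRead]]:
    """Partition reads into the three classes (secondary/duplicates dropped)."""
    out: dict[ReadClass, list[AlignedRead]] = {c: [] for c in ReadClass}
    for read in reads:
        if read.is_secondary or read.is_duplicate:
            continue
        out[classify_read(read, criteria)].append(read)
    return out


def breakpoint_pvalue(k: int, n: int, q: float) -> float:
    """Upper-tail binomial probability of seeing more than k clipped reads.

    Exactly ``1 - CDF(k)`` of Binomial(n, q); equals 0 when k = n.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0 < q < 1:
        raise ValueError(f"heterogeneity factor q must lie in (0, 1), got {q}")
    return float(binom.sf(k, n, q))


class DepthProfile:
    """Per-position count of mapped reads covering each reference base.

    Built from the aligned reference spans (M/D/=/X) of primary,
    non-duplicate mapped reads via a difference array.
    """

    def __init__(self, reference_lengths: Mapping[str, int]):
        self._diff = {name: np.zeros(length + 1, dtype=np.int32)
                      for name, length in reference_lengths.items()}
        self._depth: dict[str, np.ndarray] | None = None

    @classmethod
    def from_reads(
        cls, reads: Iterable[AlignedRead], reference_lengths: Mapping[str, int]
    ) -> "DepthProfile":
        prof = cls(reference_lengths)
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            prof.add_span(read.chrom, read.pos, read.reference_end)
        return prof

    def add_span(self, chrom: str, start: int, end: int) -> None:
        diff = self._diff[chrom]
        if start < end:
            diff[start] += 1
            diff[min(end, len(diff) - 1)] -= 1
            self._depth = None

    def _materialize(self) -> dict[str, np.ndarray]:
        if self._depth is None:
            self._depth = {
                name: np.cumsum(diff[:-1]) for name, diff in self._diff.items()
            }
        return self._depth

    def depth(self, chrom: str, pos: int) -> int:
        arr = self._materialize()[chrom]
        if not 0 <= pos < len(arr):
            return 0
        return int(arr[pos])

    def array(self, chrom: str) -> np.ndarray:
        return self._materialize()[chrom]


def _clip_positions(read: AlignedRead) -> list[tuple[int, str, int]]:
    """Yield (breakpoint coordinate, side, anchor base) per clipped end.

    The anchor base is the aligned reference base adjacent to the clip; it
    is where the local depth n is measured, so that the clipped read itself
    always counts toward n.
    """
    out = []
    cig = read.cigar
    if cig.left_clip:
        out.append((read.pos, "L", read.pos))
    if cig.right_clip:
        end = read.reference_end
        out.append((end, "R", end - 1))
    return out


def find_breakpoint_clusters(
    hq_clips: Sequence[AlignedRead],
    depth_source: DepthProfile,
    q: float = 0.1,
    alpha: float = 0.05,
    window: int = 0,
) -> list[BreakpointCluster]:
    """Group HQ soft-clipped reads by clip coordinate and keep significant clusters.

    Reads clipped at both ends contribute to two clusters.  With
    ``window`` > 0, clip coordinates within +-window of each other on the
    same side are pooled onto the most clipped coordinate.
    """
    groups: dict[tuple[str, int, str], list[tuple[AlignedRead, int]]] = {}
    for read in hq_clips:
        for bp, side, anchor in _clip_positions(read):
            groups.setdefault((read.chrom, bp, side), []).append((read, anchor))

    if window > 0:
        groups = _pool_windows(groups, window)

    clusters: list[BreakpointCluster] = []
    for (chrom, bp, side), members in sorted(groups.items()):
        k = len({read.name for read, _ in members})
        anchor = members[0][1]
        n = depth_source.depth(chrom, anchor)
        if n == 0:
            raise RuntimeError(
                f"no depth at clip locus {chrom}:{bp} despite {k} clipped reads"
            )
        n = max(n, k)
        p = breakpoint_pvalue(k, n, q)
        if p < alpha:
            clusters.append(
                BreakpointCluster(
                    chrom=chrom, position=bp, side=side, k=k, n=n, q=q,
                    p_value=p, member_reads=sorted({r.name for r, _ in members}),
                )
            )
    return clusters


def _pool_windows(groups, window):
    pooled: dict[tuple[str, int, str], list] = {}
    # Greedily absorb smaller neighbouring clusters into the largest one.
    by_size = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    taken: set[tuple[str, int, str]] = set()
    for key, members in by_size:
        if key in taken:
            continue
        chrom, bp, side = key
        merged = list(members)
        taken.add(key)
        for delta in range(-window, window + 1):
            other = (chrom, bp + delta, side)
            if delta and other in groups and other not in taken:
                merged.extend(groups[other])
                taken.add(other)
        pooled[key] = merged
    return pooled


def cluster_member_reads(
    clusters: Sequence[BreakpointCluster], hq_clips: Sequence[AlignedRead]
) -> list[AlignedRead]:
    """Unique reads belonging to any retained cluster, in input order."""
    wanted = set()
    for cluster in clusters:
        wanted.update(cluster.member_reads)
    seen: set[int] = set()
    out = []
    for read in hq_clips:
        if read.name in wanted and id(read) not in seen:
            seen.add(id(read))
            out.append(read)
    return out
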