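"""Precision/recall scoring of indel calls against a simulated truth set.

A prediction is a true positive when (i) its breakpoint lies within
``breakpoint_tolerance`` (default 100 bp) of the true breakpoint, (ii) its
size equals the true size exactly, and (iii) its type (DEL/INS) matches.
Matching is greedy one-to-one, nearest breakpoint first.  Unmatched
predictions are false positives, unmatched truths false negatives.
Precision is undefined (reported as NaN) when no predictions were made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment_core import IndelCall
from .simulator import TruthRecord


@dataclass(frozen=True)
class MatchCriteria:
    breakpoint_tolerance: int = 100
    require_exact_size: bool = True
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if self.breakpoint_tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    precision: float  # NaN when tp + fp == 0
    recall: float
    per_bin: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (bin label, tp, fn, recall-or-NaN)


def _call_breakpoint(call: IndelCall) -> int:
    """0-based first affected base of a (left-aligned) VCF call."""
    return call.breakpoint


def match_calls(
    predicted: Sequence[IndelCall],
    truth: Sequence[TruthRecord],
    criteria: MatchCriteria = MatchCriteria(),
) -> tuple[list[tuple[IndelCall, TruthRecord]], list[IndelCall], list[TruthRecord]]:
    """Greedy one-to-one matching of predictions to truth records."""
    pairs: list[tuple[int, int, int]] = []  # (distance, pred idx, truth idx)
    for pi, call in enumerate(predicted):
        for ti, t in enumerate(truth):
            if call.chrom != t.chrom:
                continue
            if criteria.require_same_type and call.svtype != t.type:
                continue
            if criteria.require_exact_size and call.size != t.size:
                continue
            dist = abs(_call_breakpoint(call) - t.start)
            if dist <= criteria.breakpoint_tolerance:
                pairs.append((dist, pi, ti))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp_pairs: list[tuple[IndelCall, TruthRecord]] = []
    for dist, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp_pairs.append((predicted[pi], truth[ti]))
    fp = [c for i, c in enumerate(predicted) if i not in used_p]
    fn = [t for i, t in enumerate(truth) if i not in used_t]
    return tp_pairs, fp, fn


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """(precision, recall); precision is NaN for an empty prediction set."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    return precision, recall


def binned_summary(
    tp_pairs: Sequence[tuple[IndelCall, TruthRecord]],
    fn_truths: Sequence[TruthRecord],
    bin_width: int = 40,
) -> list[tuple[str, int, int, float]]:
    """Per-size-bin recall: bins [1, w], (w, 2w], ...; empty bins are NaN.

    Only bins up to the largest observed truth size are reported.
    """
    sizes = [t.size for _, t in tp_pairs] + [t.size for t in fn_truths]
    if not sizes:
        return []
    n_bins = (max(sizes) - 1) // bin_width + 1
    tp_counts = [0] * n_bins
    fn_counts = [0] * n_bins
    for _, t in tp_pairs:
        tp_counts[(t.size - 1) // bin_width] += 1
    for t in fn_truths:
        fn_counts[(t.size - 1) // bin_width] += 1
    out = []
    for b in range(n_bins):
        lo, hi = b * bin_width + 1, (b + 1) * bin_width
        total = tp_counts[b] + fn_counts[b]
        recall = tp_counts[b] / total if total else math.nan
        out.append((f"{lo}-{hi}", tp_counts[b], fn_counts[b], recall))
    return out


def evaluate(
    predicted: Sequence[IndelCall],
    truth: Sequence[TruthRecord],
    criteria: MatchCriteria = MatchCriteria(),
    bin_width: int = 40,
    svtype: Optional[str] = None,
) -> BenchmarkResult:
    """Full benchmark: counts, precision/recall and the per-bin table.

    ``svtype`` restricts scoring to one event class (e.g. deletions only).
    """
    if svtype is not None:
        predicted = [c for c in predicted if c.svtype == svtype]
        truth = [t for t in truth if t.type == svtype]
    tp_pairs, fp, fn = match_calls(predicted, truth, criteria)
    precision, recall = precision_recall(len(tp_pairs), len(fp), len(fn))
    return BenchmarkResult(
        tp=len(tp_pairs),
        fp=len(fp),
        fn=len(fn),
        precision=precision,
        recall=recall,
        per_bin=binned_summary(tp_pairs, fn, bin_width),
    )
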