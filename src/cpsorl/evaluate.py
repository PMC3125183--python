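"""Per-nucleotide evaluation metrics and genome-report statistics.

Predictions and references are compared base by base: every position of the
sequence is a true positive (in both), false positive (predicted only),
false negative (reference only) or true negative (neither). From the four
counts the five standard metrics follow:

    SN  = TP / (TP + FN)                  sensitivity
    SP  = TN / (TN + FP)                  specificity
    ACC = (TP + TN) / (TP+FP+TN+FN)       accuracy
    PC  = TP / (TP + FN + FP)             performance coefficient
    CC  = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

CC is the Matthews-style per-base correlation. Counts are computed by
interval arithmetic (merge + intersection), never by materializing per-base
arrays, so chromosome-scale inputs are cheap.

Report statistics mirror the usual genome-survey tables: island count,
total/average/min/max length, percent coverage of the sequence, GC and O/E
means with population SDs, methylation density (sites inside islands per
island bp, as %), and TSS / promoter overlap counts with the promoter
defined as -1500..+500 bp around the TSS (orientation-flipped on the minus
strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .refine import CpGIsland
from .sequence import CoordinateError, GenomeSequence, Interval

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-base TP/FP/TN/FN; the four always sum to the evaluated length."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """SN/SP/ACC/PC/CC; an undefined metric (zero denominator) is NaN."""

    SN: float
    SP: float
    ACC: float
    PC: float
    CC: float


@dataclass(frozen=True)
class IslandReport:
    n_islands: int
    total_length: int
    avg_length: float
    min_length: int
    max_length: int
    coverage: float  # % of sequence
    gc_mean: float
    gc_sd: float
    oe_mean: float
    oe_sd: float
    methylation_density: Optional[float] = None  # %
    tss_overlap: Optional[int] = None
    promoter_overlap: Optional[int] = None


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted disjoint list."""
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def _intersection_length(a: list[Interval], b: list[Interval]) -> int:
    """Total overlap of two disjoint sorted interval lists (two-pointer scan)."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if hi > lo:
            total += hi - lo
        if a[i].end <= b[j].end:
            i += 1
        else:
            j += 1
    return total


def confusion_counts(
    predicted: Sequence[Interval], reference: Sequence[Interval], L: int
) -> ConfusionCounts:
    """Per-base confusion counts over a sequence of length L."""
    for iv in list(predicted) + list(reference):
        if iv.end > L:
            raise CoordinateError(f"interval [{iv.start},{iv.end}) outside [0,{L})")
    pred = merge_intervals(predicted)
    ref = merge_intervals(reference)
    pred_len = sum(iv.length for iv in pred)
    ref_len = sum(iv.length for iv in ref)
    tp = _intersection_length(pred, ref)
    fp = pred_len - tp
    fn = ref_len - tp
    tn = L - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five per-base metrics; zero-denominator cases come back as NaN."""
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    denom_cc = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    cc = (tp * tn - fn * fp) / denom_cc if denom_cc > 0 else math.nan
    return MetricsReport(
        SN=_ratio(tp, tp + fn),
        SP=_ratio(tn, tn + fp),
        ACC=_ratio(tp + tn, c.total),
        PC=_ratio(tp, tp + fn + fp),
        CC=cc,
    )


def roc_points(
    islands: Sequence[CpGIsland],
    reference: Sequence[Interval],
    L: int,
    thresholds: Sequence[float],
) -> list[tuple[float, float]]:
    """(FPR, TPR) per fitness threshold, sorted by FPR.

    An island counts as predicted at a threshold when its fitness reaches it.
    """
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds for a ROC sweep")
    points = []
    for t in thresholds:
        kept = [isl.interval for isl in islands if isl.fitness >= t]
        c = confusion_counts(kept, reference, L)
        fpr = _ratio(c.FP, c.FP + c.TN)
        tpr = _ratio(c.TP, c.TP + c.FN)
        points.append((fpr, tpr))
    return sorted(points)


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC point sequence sorted by FPR."""
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    return float(np.trapezoid(tpr, fpr))


def coverage(total_island_length: int, L: int) -> float:
    """Percent of the sequence covered by islands (full precision)."""
    if L <= 0:
        raise ValueError("sequence length must be positive")
    if not 0 <= total_island_length <= L:
        raise ValueError("total island length outside [0, L]")
    return 100.0 * total_island_length / L


def methylation_density(sites_in_islands: int, total_island_length: int) -> float:
    """Methylation sites per island bp, as a percentage."""
    if total_island_length <= 0:
        return math.nan
    return 100.0 * sites_in_islands / total_island_length


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (genome-table display
    convention for densities: 6.9160 prints as 6.91)."""
    scale = 10 ** decimals
    return math.trunc(value * scale) / scale


def _points_in_intervals(points: np.ndarray, intervals: list[Interval]) -> np.ndarray:
    """Boolean mask: which points fall inside the union of intervals."""
    if not intervals or points.size == 0:
        return np.zeros(points.shape, dtype=bool)
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(points.shape, dtype=bool)
    hit[ok] = points[ok] < ends[idx[ok]]
    return hit


def tss_promoter_overlap(
    islands: Sequence[CpGIsland],
    tss_positions: Sequence[int],
    strands: Optional[Sequence[str]] = None,
    L: Optional[int] = None,
) -> tuple[int, int]:
    """Counts of TSSs inside an island, and of promoters touching an island.

    The promoter is [TSS-1500, TSS+500) on the plus strand and
    [TSS-500+1, TSS+1500+1) on the minus strand (the same window read on the
    other orientation). Promoter overlap requires >= 1 bp shared with an
    island.
    """
    merged = merge_intervals([isl.interval for isl in islands])
    pts = np.asarray(tss_positions, dtype=np.int64)
    if strands is None:
        strands = ["+"] * len(pts)
    tss_count = int(_points_in_intervals(pts, merged).sum())
    promoter_count = 0
    for pos, strand in zip(pts, strands):
        if strand == "-":
            lo, hi = pos - PROMOTER_DOWNSTREAM + 1, pos + PROMOTER_UPSTREAM + 1
        else:
            lo, hi = pos - PROMOTER_UPSTREAM, pos + PROMOTER_DOWNSTREAM
        lo = max(lo, 0)
        if L is not None:
            hi = min(hi, L)
        if hi <= lo:
            continue
        prom = [Interval(lo, hi)]
        if _intersection_length(merged, prom) >= 1:
            promoter_count += 1
    return tss_count, promoter_count


def island_report(
    islands: Sequence[CpGIsland],
    seq: GenomeSequence,
    methylation_positions: Optional[Sequence[int]] = None,
    tss_positions: Optional[Sequence[int]] = None,
    tss_strands: Optional[Sequence[str]] = None,
) -> IslandReport:
    """Summary-table statistics for a set of predicted islands."""
    n = len(islands)
    if n == 0:
        return IslandReport(
            n_islands=0, total_length=0, avg_length=math.nan,
            min_length=0, max_length=0, coverage=0.0,
            gc_mean=math.nan, gc_sd=math.nan, oe_mean=math.nan, oe_sd=math.nan,
            methylation_density=(math.nan if methylation_positions is not None else None),
            tss_overlap=(0 if tss_positions is not None else None),
            promoter_overlap=(0 if tss_positions is not None else None),
        )
    lengths = np.array([isl.length for isl in islands])
    gcs = np.array([isl.gc for isl in islands])
    oes = np.array([isl.oe for isl in islands])
    total = int(lengths.sum())
    meth = None
    if methylation_positions is not None:
        merged = merge_intervals([isl.interval for isl in islands])
        inside = _points_in_intervals(
            np.asarray(methylation_positions, dtype=np.int64), merged
        )
        meth = methylation_density(int(inside.sum()), total)
    tss_n = prom_n = None
    if tss_positions is not None:
        tss_n, prom_n = tss_promoter_overlap(
            islands, tss_positions, tss_strands, L=seq.length
        )
    return IslandReport(
        n_islands=n,
        total_length=total,
        avg_length=total / n,
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        coverage=coverage(total, seq.length),
        gc_mean=float(gcs.mean()),
        gc_sd=float(gcs.std()),  # population SD
        oe_mean=float(oes.mean()),
        oe_sd=float(oes.std()),
        methylation_density=meth,
        tss_overlap=tss_n,
        promoter_overlap=prom_n,
    )


def format_report(report: IslandReport, name: str = "") -> str:
    """Human-readable report; coverage to 1 decimal, density to 2, lengths floored."""
    def fmt(v, spec):
        return "NA" if v is None or (isinstance(v, float) and math.isnan(v)) else format(v, spec)

    lines = [
        f"CpG island report{(' for ' + name) if name else ''}",
        f"  islands predicted      : {report.n_islands}",
        f"  total length (bp)      : {report.total_length}",
        f"  average length (bp)    : {fmt(None if report.n_islands == 0 else int(report.avg_length), 'd')}",
        f"  min / max length (bp)  : {report.min_length} / {report.max_length}",
        f"  coverage (%)           : {fmt(report.coverage, '.1f')}",
        f"  GC content ± SD        : {fmt(report.gc_mean, '.4f')} ± {fmt(report.gc_sd, '.4f')}",
        f"  O/E ratio ± SD         : {fmt(report.oe_mean, '.4f')} ± {fmt(report.oe_sd, '.4f')}",
    ]
    if report.methylation_density is not None:
        dens = report.methylation_density
        dens = truncate(dens, 2) if not math.isnan(dens) else dens
        lines.append(f"  methylation density (%) : {fmt(dens, '.2f')}")
    if report.tss_overlap is not None:
        lines.append(f"  TSSs in islands        : {report.tss_overlap}")
        lines.append(f"  promoters overlapping  : {report.promoter_overlap}")
    return "\n".join(lines)
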