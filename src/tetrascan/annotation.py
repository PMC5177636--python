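"""Coding-density statistics and cross-clone correlation.

Computes the fraction of a fragment covered by protein-coding intervals
(overlaps merged so each base counts once) and the Pearson correlation,
with its two-sided t-test p-value, between per-clone coding percentage
and the mean internal tetranucleotide correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import FeatureInterval, SequenceRecord, gc_content
from .tetra import CorrelationMatrix


@dataclass(frozen=True)
class CloneSummary:
    """Per-clone sequence and signature statistics."""

    seq_id: str
    length: int
    gc_percent: float
    n_orfs: int
    coding_percent: float
    mean_r: float
    sd_r: float


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between two clone-level variables with a
    two-sided p-value from t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2."""

    n: int
    r: float
    p: float
    variable_x: str
    variable_y: str


def merge_intervals(intervals: Iterable[FeatureInterval]) -> list[tuple[int, int]]:
    """Merge overlapping (or book-ended) intervals into disjoint spans."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coding_percent(intervals: Iterable[FeatureInterval], length: int) -> float:
    """Percentage of the fragment covered by the given intervals.

    Overlapping intervals are merged first so each base is counted once.
    """
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    intervals = list(intervals)
    for iv in intervals:
        if iv.end > length:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}] exceeds sequence length {length}"
            )
    covered = sum(e - s + 1 for s, e in merge_intervals(intervals))
    return 100.0 * covered / length


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient at sample size n.

    Uses the exact t-transform t = r*sqrt(n-2)/sqrt(1-r^2) against the
    t-distribution with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_clones(
    summaries: Sequence[CloneSummary],
    x: str = "coding_percent",
    y: str = "mean_r",
) -> CorrelationReport:
    """Pearson correlation between two numeric clone-summary fields."""
    if len(summaries) < 3:
        raise ValueError(f"need at least 3 clones, got {len(summaries)}")
    xs = np.array([float(getattr(s, x)) for s in summaries])
    ys = np.array([float(getattr(s, y)) for s in summaries])
    for name, values in ((x, xs), (y, ys)):
        if np.ptp(values) == 0:
            raise ValueError(f"variable {name!r} is constant across clones")
    r = float(stats.pearsonr(xs, ys).statistic)
    return CorrelationReport(
        n=len(summaries), r=r, p=pearson_pvalue(r, len(summaries)), variable_x=x, variable_y=y
    )


def build_summary(
    record: SequenceRecord,
    intervals: Iterable[FeatureInterval],
    matrix: CorrelationMatrix,
) -> CloneSummary:
    """Join sequence, annotation and signature statistics for one clone.

    Only CDS intervals count toward coding percentage (rRNA is annotated
    separately and is not coding).
    """
    if matrix.seq_id != record.id:
        raise ValueError(
            f"matrix is for {matrix.seq_id!r} but record is {record.id!r}"
        )
    intervals = list(intervals)
    for iv in intervals:
        if iv.seq_id != record.id:
            raise ValueError(
                f"interval on {iv.seq_id!r} does not belong to record {record.id!r}"
            )
    cds = [iv for iv in intervals if iv.kind == "CDS"]
    return CloneSummary(
        seq_id=record.id,
        length=len(record.seq),
        gc_percent=gc_content(record.seq),
        n_orfs=len(cds),
        coding_percent=coding_percent(cds, len(record.seq)),
        mean_r=matrix.mean_r,
        sd_r=matrix.sd_r,
    )
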