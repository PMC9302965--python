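"""Shared vs set-specific peak accounting, genomic-context annotation,
peak-shape metrics, and between-sample distances.

``classify_peaks`` consumes a merged consensus set whose peaks carry
contributed-by provenance and splits it into shared / a-only / b-only with
percentage accounting.  ``annotate_features`` applies the 40 %-overlap rule
used for genomic-context assignment, with a fixed precedence when several
features qualify (promoter > utr5 > utr3 > exon > intron).  ``shape_metrics``
summarizes a peak's coverage profile as summit height and width-at-half-max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .intervals import (
    FEATURE_PRECEDENCE,
    GenomicInterval,
    IntervalIndex,
    Peak,
    ValidationError,
)
from .peak_consensus import ConsensusPeakSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    total: int
    shared: int
    a_only: int
    b_only: int

    def __post_init__(self) -> None:
        if self.shared + self.a_only + self.b_only != self.total:
            raise ValidationError("comparison counts do not partition the total")

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.shared / self.total

    @property
    def pct_a_only(self) -> float:
        return 100.0 * self.a_only / self.total

    @property
    def pct_b_only(self) -> float:
        return 100.0 * self.b_only / self.total

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "shared": self.shared,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "pct_shared": self.pct_shared,
            "pct_a_only": self.pct_a_only,
            "pct_b_only": self.pct_b_only,
        }


@dataclass(frozen=True)
class ShapeMetrics:
    summit_height: float
    base_width: int


def classify_peaks(
    merged: ConsensusPeakSet, label_a: str, label_b: str
) -> tuple[ComparisonResult, list[str]]:
    """Label each merged peak shared / a_only / b_only from its provenance."""
    labels: list[str] = []
    for cp in merged:
        if not cp.sources:
            raise ValidationError("merged peak lacks contributed-by provenance")
        has_a = label_a in cp.sources
        has_b = label_b in cp.sources
        if has_a and has_b:
            labels.append("shared")
        elif has_a:
            labels.append("a_only")
        elif has_b:
            labels.append("b_only")
        else:
            raise ValidationError(
                f"peak provenance {set(cp.sources)} matches neither input label"
            )
    result = ComparisonResult(
        total=len(labels),
        shared=labels.count("shared"),
        a_only=labels.count("a_only"),
        b_only=labels.count("b_only"),
    )
    return result, labels


def annotate_features(
    intervals, features, min_frac: float = 0.4
) -> list[str]:
    """Assign each interval the highest-precedence feature covering >= 40 % of it.

    The denominator is the interval's own length; an interval meeting the
    threshold for no feature is ``distal``.
    """
    idx = IntervalIndex((f.interval, f) for f in features)
    rank = {lab: i for i, lab in enumerate(FEATURE_PRECEDENCE)}
    labels = []
    for iv in intervals:
        iv = iv.interval if hasattr(iv, "interval") else iv
        best = "distal"
        for f in idx.overlapping(iv):
            if f.interval.overlap_bp(iv) >= min_frac * len(iv):
                if rank[f.label] < rank[best]:
                    best = f.label
        labels.append(best)
    return labels


def coverage_profile(fragments, interval: GenomicInterval) -> np.ndarray:
    """Per-bp fragment coverage restricted to the interval."""
    cov = np.zeros(len(interval))
    for f in fragments:
        a = max(f.start, interval.start)
        b = min(f.end, interval.end)
        if f.chrom == interval.chrom and b > a:
            cov[a - interval.start : b - interval.start] += 1
    return cov


def shape_metrics(fragments, peak: Peak) -> ShapeMetrics:
    """Summit height and width-at-half-max of a peak's coverage profile.

    base_width is the maximal contiguous run containing the coverage argmax
    with coverage >= half the summit height (robust to multi-modal noise).
    """
    cov = coverage_profile(fragments, peak.interval)
    height = cov.max()
    if height <= 0:
        raise ValidationError("shape_metrics requires >= 1 overlapping fragment")
    apex = int(cov.argmax())
    half = height / 2.0
    lo = apex
    while lo > 0 and cov[lo - 1] >= half:
        lo -= 1
    hi = apex
    while hi < len(cov) - 1 and cov[hi + 1] >= half:
        hi += 1
    return ShapeMetrics(summit_height=float(height), base_width=hi - lo + 1)


def sample_distance_matrix(counts: pd.DataFrame, log_scale: bool = False) -> pd.DataFrame:
    """Pairwise Euclidean distances between per-sample count vectors.

    Rows are peaks, columns samples.  ``log_scale`` applies log1p first.
    """
    if counts.shape[1] < 2:
        raise ValidationError("sample_distance_matrix requires >= 2 samples")
    if (counts.values < 0).any():
        raise ValidationError("counts must be non-negative")
    mat = counts.values.T.astype(float)
    if log_scale:
        mat = np.log1p(mat)
    dist = squareform(pdist(mat, metric="euclidean"))
    return pd.DataFrame(dist, index=counts.columns, columns=counts.columns)


def differential_rank(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, pseudocount: float = 1.0
) -> pd.Series:
    """Per-peak log2 fold change of mean CPM (a vs b), descending.

    A deliberately non-statistical ranking (no dispersion model, no
    p-values): CPM-normalize each sample, average within group, and rank by
    ``log2((mean_cpm_a + c) / (mean_cpm_b + c))`` with c = 1.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValidationError("count tables must share the same peak ids")
    for df in (counts_a, counts_b):
        totals = df.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("every sample needs a positive total count")
    cpm_a = counts_a / counts_a.sum(axis=0) * 1e6
    cpm_b = counts_b / counts_b.sum(axis=0) * 1e6
    lfc = np.log2((cpm_a.mean(axis=1) + pseudocount) / (cpm_b.mean(axis=1) + pseudocount))
    return lfc.sort_values(ascending=False)
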