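"""Fixed-width, reproducible consensus peak sets.

The workflow turns per-sample peak calls into one high-confidence set per
condition/platform:

1. Summits are extended by 250 bp per side into 501 bp fixed-width peaks;
   windows crossing a chromosome boundary are dropped (clipping would break
   the fixed-width arithmetic the 50 %-overlap rule relies on).
2. Peaks intersecting a blacklist region by >= 1 bp are removed.
3. Overlapping peaks within a sample are resolved by iterative removal:
   repeatedly keep the most significant remaining peak and discard every
   peak overlapping it (>= 1 bp).  Ties are broken by (chrom, start,
   sample_id), smallest kept, so the result is deterministic.
4. Scores are converted to score-per-million (SPM):
   ``spm_i = score_i / (sum(scores) / 1e6)``, so each sample's SPM vector
   sums to exactly 1e6 and scores become comparable across libraries of
   different depth/quality.
5. Replicate consensus: all samples' peaks are pooled, iterative removal is
   run on the pool ranked by SPM, and each survivor is kept only if peaks
   with SPM >= 3 from at least two distinct samples overlap it by at least
   50 % of the fixed width (the survivor counts toward its own support when
   it qualifies).
6. Cross-set consensus: each input set's SPM vector is re-normalized to sum
   to 1e6 (so deeper/higher-quality sets are not over-represented), the sets
   are pooled, and iterative removal is run again.  Each surviving peak
   records which input sets contributed a >= 50 %-overlapping peak, which
   drives the shared / set-specific accounting downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    Peak,
    PeakSet,
    ValidationError,
)

log = logging.getLogger(__name__)

SPM_TOTAL = 1_000_000.0


@dataclass(frozen=True)
class ConsensusParams:
    extension: int = 250
    min_spm: float = 3.0
    min_samples: int = 2
    min_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_frac <= 1):
            raise ValidationError("min_overlap_frac must be in (0, 1]")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")

    @property
    def width(self) -> int:
        return 2 * self.extension + 1


@dataclass(frozen=True)
class ConsensusPeak:
    """A surviving consensus peak with its reproducibility provenance."""

    peak: Peak
    support: int
    sources: frozenset = frozenset()

    @property
    def interval(self) -> GenomicInterval:
        return self.peak.interval

    @property
    def spm(self) -> float:
        return self.peak.spm


@dataclass
class ConsensusPeakSet:
    label: str
    peaks: list[ConsensusPeak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def as_peakset(self) -> PeakSet:
        return PeakSet(sample_id=self.label, peaks=[cp.peak for cp in self.peaks])


def to_fixed_width(
    peakset: PeakSet, chrom_sizes: dict[str, int], extension: int = 250
) -> PeakSet:
    """Extend each summit by ``extension`` bp per side (width 2*ext+1).

    Peaks whose window would cross a chromosome boundary are dropped; the
    count is logged.
    """
    out: list[Peak] = []
    dropped = 0
    for p in peakset:
        if p.summit is None:
            raise ValidationError(f"peak {p.name} has no summit")
        size = chrom_sizes.get(p.chrom)
        if size is None:
            raise ValidationError(f"unknown chromosome {p.chrom!r}")
        start = p.summit - extension
        end = p.summit + extension + 1
        if start < 0 or end > size:
            dropped += 1
            continue
        out.append(replace(p, interval=GenomicInterval(p.chrom, start, end)))
    if dropped:
        log.info("to_fixed_width[%s]: dropped %d boundary peaks", peakset.sample_id, dropped)
    return PeakSet(
        sample_id=peakset.sample_id,
        peaks=out,
        condition=peakset.condition,
        platform=peakset.platform,
    )


def filter_blacklist(peakset: PeakSet, blacklist: Sequence[GenomicInterval]) -> PeakSet:
    """Remove peaks intersecting any blacklist interval by >= 1 bp."""
    idx = IntervalIndex((iv, None) for iv in blacklist)
    kept = [p for p in peakset if not idx.any_overlap(p.interval)]
    removed = len(peakset) - len(kept)
    if removed:
        log.info("filter_blacklist[%s]: removed %d peaks", peakset.sample_id, removed)
    return PeakSet(
        sample_id=peakset.sample_id,
        peaks=kept,
        condition=peakset.condition,
        platform=peakset.platform,
    )


def _removal_key(score_of, p: Peak):
    return (-score_of(p), p.chrom, p.start, p.sample_id)


def iterative_removal(peakset: PeakSet, by_spm: bool = False) -> PeakSet:
    """Greedy-by-score overlap resolution.

    Equivalent to: repeatedly keep the most significant remaining peak and
    discard all peaks overlapping it (>= 1 bp) until none remain.  A single
    score-ordered sweep against the kept set realizes the same survivor set
    in O(n log n).  Equal scores are broken by (chrom, start, sample_id),
    smallest kept.
    """
    score_of = (lambda p: p.spm) if by_spm else (lambda p: p.score)
    ordered = sorted(peakset.peaks, key=lambda p: _removal_key(score_of, p))
    kept_idx = IntervalIndex()
    kept: list[Peak] = []
    for p in ordered:
        if not kept_idx.any_overlap(p.interval):
            kept.append(p)
            kept_idx.add(p.interval, None)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(
        sample_id=peakset.sample_id,
        peaks=kept,
        condition=peakset.condition,
        platform=peakset.platform,
    )


def spm_normalize(scores) -> np.ndarray:
    """Score-per-million: score_i / (sum(scores) / 1e6); output sums to 1e6."""
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any():
        raise ValidationError("scores must be >= 0")
    total = scores.sum()
    if total <= 0:
        raise ValidationError("sum of scores must be > 0 for SPM normalization")
    return scores / (total / SPM_TOTAL)


def spm_normalize_peakset(peakset: PeakSet) -> PeakSet:
    spms = spm_normalize(peakset.scores())
    return PeakSet(
        sample_id=peakset.sample_id,
        peaks=[p.with_spm(s) for p, s in zip(peakset.peaks, spms)],
        condition=peakset.condition,
        platform=peakset.platform,
    )


def _overlap_threshold(width: int, frac: float) -> int:
    return math.ceil(frac * width)


def replicate_consensus(
    samples: Sequence[PeakSet],
    params: ConsensusParams = ConsensusParams(),
    label: str = "",
) -> ConsensusPeakSet:
    """Reproducible consensus across replicate samples.

    Requires each input to be fixed-width, blacklist-filtered, internally
    non-overlapping, and SPM-normalized.  Pools all peaks, runs iterative
    removal ranked by SPM, then keeps survivors supported by >= min_samples
    distinct samples whose own peak has SPM >= min_spm and overlaps the
    survivor by >= min_overlap_frac of the fixed width.
    """
    if len(samples) < params.min_samples:
        raise ValidationError(
            f"replicate_consensus needs >= {params.min_samples} samples, got {len(samples)}"
        )
    pooled: list[Peak] = []
    for s in samples:
        for p in s:
            if p.spm is None:
                raise ValidationError(f"sample {s.sample_id} is not SPM-normalized")
            pooled.append(p)
    survivors = iterative_removal(PeakSet(sample_id=label, peaks=pooled), by_spm=True)

    qualifying = IntervalIndex(
        (p.interval, p) for p in pooled if p.spm >= params.min_spm
    )
    out: list[ConsensusPeak] = []
    for sv in survivors:
        need = _overlap_threshold(sv.width, params.min_overlap_frac)
        supporters = {
            q.sample_id
            for q in qualifying.overlapping(sv.interval)
            if q.interval.overlap_bp(sv.interval) >= need
        }
        if len(supporters) >= params.min_samples:
            out.append(ConsensusPeak(peak=sv, support=len(supporters)))
    log.info(
        "replicate_consensus[%s]: %d pooled -> %d survivors -> %d reproducible",
        label, len(pooled), len(survivors), len(out),
    )
    return ConsensusPeakSet(label=label, peaks=out)


def renormalize_spm(cset: ConsensusPeakSet) -> ConsensusPeakSet:
    """Re-scale a consensus set's SPM vector so it sums to 1e6 again."""
    if len(cset) == 0:
        raise ValidationError("cannot re-normalize an empty consensus set")
    spms = spm_normalize([cp.spm for cp in cset])
    return ConsensusPeakSet(
        label=cset.label,
        peaks=[
            ConsensusPeak(peak=cp.peak.with_spm(s), support=cp.support, sources=cp.sources)
            for cp, s in zip(cset.peaks, spms)
        ],
    )


def merge_consensus_sets(
    sets: Sequence[ConsensusPeakSet],
    params: ConsensusParams = ConsensusParams(),
    label: str = "merged",
) -> ConsensusPeakSet:
    """Cross-set consensus with per-set SPM re-normalization.

    Each surviving peak's ``sources`` records the input sets that contributed
    a peak overlapping it by >= min_overlap_frac of its width.
    """
    if len(sets) < 2:
        raise ValidationError("merge_consensus_sets needs >= 2 input sets")
    renormed = [renormalize_spm(s) for s in sets]

    pooled: list[Peak] = []
    for cs in renormed:
        for cp in cs:
            pooled.append(replace(cp.peak, sample_id=cs.label))
    survivors = iterative_removal(PeakSet(sample_id=label, peaks=pooled), by_spm=True)

    idx = IntervalIndex((p.interval, p) for p in pooled)
    out: list[ConsensusPeak] = []
    for sv in survivors:
        need = _overlap_threshold(sv.width, params.min_overlap_frac)
        sources = frozenset(
            q.sample_id
            for q in idx.overlapping(sv.interval)
            if q.interval.overlap_bp(sv.interval) >= need
        )
        out.append(ConsensusPeak(peak=sv, support=len(sources), sources=sources))
    return ConsensusPeakSet(label=label, peaks=out)
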