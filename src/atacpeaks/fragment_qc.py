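"""Library-quality statistics for ATAC-seq fragment sets.

Insert sizes of Tn5-fragmented accessible chromatin fall in a downward
ladder: nucleosome-free/sub-nucleosomal (< 147 bp), mono-nucleosomal
(180-247 bp) and di-nucleosomal (315-473 bp) fragments.  Lengths in the
gaps (147-179, 248-314, > 473 bp) form an explicit ``other`` class so the
reported proportions always partition.

Signal-to-background metrics:

* FROT — fraction of fragments within +/- 1 kb of any TSS.
* FRiP — three-way partition of fragments into TSS-proximal peaks, distal
  peaks and not-in-peaks; a peak is proximal when it intersects a
  TSS +/- 1 kb window, and a fragment under both kinds of peak is counted
  as proximal.

Fragments (sequenced pairs), not read mates, are the counting unit
throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    Fragment,
    GenomicInterval,
    IntervalIndex,
    PeakSet,
    TssRecord,
    ValidationError,
    pairwise_nonoverlapping,
)

log = logging.getLogger(__name__)

SIZE_CLASSES = ("sub", "mono", "di", "other")


@dataclass(frozen=True)
class SizeClassScheme:
    """Fragment-length class boundaries (bp)."""

    sub_max: int = 147  # exclusive: sub-nucleosomal is < 147
    mono_lo: int = 180
    mono_hi: int = 247  # inclusive
    di_lo: int = 315
    di_hi: int = 473  # inclusive

    def __post_init__(self) -> None:
        if not (self.sub_max <= self.mono_lo <= self.mono_hi < self.di_lo <= self.di_hi):
            raise ValidationError("size class bounds must be ordered")


@dataclass
class QcReport:
    n_fragments: int
    class_proportions: dict[str, float]
    frot: float
    frip: dict[str, float]
    tss_profile: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "class_proportions": self.class_proportions,
            "frot": self.frot,
            "frip": self.frip,
            "tss_profile": list(self.tss_profile),
        }


def classify_fragment_length(length: int, scheme: SizeClassScheme = SizeClassScheme()) -> str:
    """Assign a fragment length to exactly one of sub/mono/di/other."""
    if length <= 0:
        raise ValidationError(f"fragment length must be >= 1, got {length}")
    if length < scheme.sub_max:
        return "sub"
    if scheme.mono_lo <= length <= scheme.mono_hi:
        return "mono"
    if scheme.di_lo <= length <= scheme.di_hi:
        return "di"
    return "other"


def size_distribution(
    fragments, scheme: SizeClassScheme = SizeClassScheme()
) -> tuple[dict[int, int], dict[str, float]]:
    """Per-length histogram and size-class proportions.

    Returns ``(histogram, proportions)`` where proportions sum to 1 over
    the four classes.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValidationError("size_distribution requires >= 1 fragment")
    hist = Counter(f.length for f in fragments)
    counts = Counter(classify_fragment_length(n, scheme) for n in hist.elements())
    total = sum(counts.values())
    proportions = {c: counts.get(c, 0) / total for c in SIZE_CLASSES}
    return dict(hist), proportions


def _tss_window_index(tss_records, window: int) -> IntervalIndex:
    idx = IntervalIndex()
    for t in tss_records:
        idx.add(GenomicInterval(t.chrom, max(0, t.pos - window), t.pos + window + 1), t)
    return idx


def frot(fragments, tss_records, window: int = 1000) -> float:
    """Fraction of fragments intersecting any TSS +/- window by >= 1 bp."""
    fragments = list(fragments)
    if not fragments:
        raise ValidationError("frot requires >= 1 fragment")
    tss_records = list(tss_records)
    if not tss_records:
        log.warning("frot: empty TSS set; returning 0")
        return 0.0
    idx = _tss_window_index(tss_records, window)
    n_hit = sum(1 for f in fragments if idx.any_overlap(f.interval))
    return n_hit / len(fragments)


def tss_profile(fragments, tss_records, window: int = 1000, bin: int = 10) -> np.ndarray:
    """Mean per-bin fragment coverage across strand-oriented TSS windows.

    Each TSS contributes a ``[pos-window, pos+window)`` window; minus-strand
    windows are reversed so upstream is always on the left.  Coverage is the
    per-bp fragment depth averaged within each bin and across TSS windows.
    """
    if window % bin != 0:
        raise ValidationError("window must be divisible by bin")
    n_bins = 2 * window // bin
    tss_records = list(tss_records)
    if not tss_records:
        return np.zeros(n_bins)

    frag_idx = IntervalIndex((f.interval, f) for f in fragments)
    profile = np.zeros(n_bins)
    for t in tss_records:
        lo, hi = t.pos - window, t.pos + window
        cov = np.zeros(2 * window)
        query = GenomicInterval(t.chrom, max(0, lo), hi)
        for f in frag_idx.overlapping(query):
            a = max(f.start, lo) - lo
            b = min(f.end, hi) - lo
            if b > a >= 0:
                cov[a:b] += 1
        if t.strand == "-":
            cov = cov[::-1]
        profile += cov.reshape(n_bins, bin).mean(axis=1)
    return profile / len(tss_records)


def frip(fragments, peaks: PeakSet, tss_records, window: int = 1000) -> dict[str, float]:
    """Partition fragments into {tss_peaks, distal_peaks, not_in_peaks}.

    Peaks are first labeled proximal (intersecting any TSS +/- window) or
    distal; each fragment then lands in exactly one category, checking
    proximal peaks first.
    """
    fragments = list(fragments)
    if len(peaks) == 0:
        raise ValidationError("frip requires a non-empty peak set")
    tss_idx = _tss_window_index(tss_records, window)
    proximal = IntervalIndex()
    distal = IntervalIndex()
    for p in peaks:
        (proximal if tss_idx.any_overlap(p.interval) else distal).add(p.interval, p)

    counts = {"tss_peaks": 0, "distal_peaks": 0, "not_in_peaks": 0}
    for f in fragments:
        if proximal.any_overlap(f.interval):
            counts["tss_peaks"] += 1
        elif distal.any_overlap(f.interval):
            counts["distal_peaks"] += 1
        else:
            counts["not_in_peaks"] += 1
    total = max(1, len(fragments))
    return {k: v / total for k, v in counts.items()}


def count_in_peaks(fragments, peaks: PeakSet) -> np.ndarray:
    """Fragments intersecting each peak by >= 1 bp (peaks must not overlap)."""
    peak_list = list(peaks)
    if not pairwise_nonoverlapping(peak_list):
        raise ValidationError("count_in_peaks requires pairwise non-overlapping peaks")
    idx = IntervalIndex((p.interval, i) for i, p in enumerate(peak_list))
    counts = np.zeros(len(peak_list), dtype=np.int64)
    for f in fragments:
        for i in idx.overlapping(f.interval):
            counts[i] += 1
    return counts


def subsample_fragments(fragments, n: int, seed: int) -> list[Fragment]:
    """Uniform random subset of exactly n fragments (reproducible by seed)."""
    fragments = list(fragments)
    if n > len(fragments):
        raise ValidationError(
            f"cannot subsample {n} from {len(fragments)} fragments"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(fragments), size=n, replace=False)
    keep.sort()
    return [fragments[i] for i in keep]


def qc_report(
    fragments,
    peaks: PeakSet,
    tss_records,
    window: int = 1000,
    bin: int = 10,
    scheme: SizeClassScheme = SizeClassScheme(),
) -> QcReport:
    """Bundle all QC statistics for one library."""
    fragments = list(fragments)
    _, proportions = size_distribution(fragments, scheme)
    return QcReport(
        n_fragments=len(fragments),
        class_proportions=proportions,
        frot=frot(fragments, tss_records, window),
        frip=frip(fragments, peaks, tss_records, window),
        tss_profile=list(tss_profile(fragments, tss_records, window, bin)),
    )
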