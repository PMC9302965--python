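"""Core genomic record types shared by every pipeline stage.

All coordinates are 0-based, half-open (BED native): an interval covers
positions ``start .. end-1`` and a peak of width 501 centred on summit ``s``
spans ``[s-250, s+251)``.  No other module re-interprets coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

FEATURE_LABELS = ("promoter", "utr5", "exon", "intron", "utr3", "distal")

#: Precedence when several features satisfy the overlap rule (highest first).
FEATURE_PRECEDENCE = ("promoter", "utr5", "utr3", "exon", "intron", "distal")


class ValidationError(ValueError):
    """Raised when a record or operation precondition is violated."""


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection in bp (0 when disjoint or trans)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) >= 1


@dataclass(frozen=True)
class Peak:
    """A scored peak call: interval, summit, -log10(p) score, optional SPM."""

    interval: GenomicInterval
    summit: int
    score: float
    spm: Optional[float] = None
    sample_id: str = ""
    name: str = "."
    strand: str = "."
    signal: float = 0.0
    qvalue: float = -1.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValidationError(f"score must be >= 0, got {self.score}")
        if self.spm is not None and self.spm < 0:
            raise ValidationError(f"spm must be >= 0, got {self.spm}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return len(self.interval)

    def with_spm(self, spm: float) -> "Peak":
        return replace(self, spm=spm)


@dataclass
class PeakSet:
    """All peaks of one sample (or one pooled/consensus stage)."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    condition: str = ""
    platform: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def scores(self) -> list[float]:
        return [p.score for p in self.peaks]

    def spms(self) -> list[float]:
        return [p.spm for p in self.peaks if p.spm is not None]


@dataclass(frozen=True)
class Fragment:
    """A sequenced insert; its length drives nucleosomal classification."""

    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class FeatureInterval:
    interval: GenomicInterval
    label: str

    def __post_init__(self) -> None:
        if self.label not in FEATURE_LABELS:
            raise ValidationError(
                f"unknown feature label {self.label!r}; "
                f"expected one of {FEATURE_LABELS}"
            )


class IntervalIndex:
    """Per-chromosome interval lookup backed by ``intervaltree``.

    Stores arbitrary payloads; queries return payloads of intervals that
    intersect the query by >= 1 bp.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        from intervaltree import IntervalTree

        self._trees: dict[str, IntervalTree] = {}
        self._IntervalTree = IntervalTree
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object = None) -> None:
        tree = self._trees.setdefault(iv.chrom, self._IntervalTree())
        tree.addi(iv.start, iv.end, payload)

    def overlapping(self, iv: GenomicInterval) -> list[object]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))


def pairwise_nonoverlapping(peaks: Sequence[Peak]) -> bool:
    """True if no two peaks intersect by >= 1 bp (sweep per chromosome)."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom_peaks in by_chrom.values():
        chrom_peaks.sort(key=lambda p: p.start)
        for a, b in zip(chrom_peaks, chrom_peaks[1:]):
            if b.start < a.end:
                return False
    return True
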