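"""Synthetic ATAC-seq study generator with ground truth.

Emulates the statistical structure of a two-cell-type (mESC vs MEF),
two-sequencing-platform (Illumina vs BGI), three-replicate ATAC-seq
comparison at desk scale:

* planted accessible regions, most shared between the two cell states and
  the rest state-specific, with per-region strength so some regions sit near
  the detection limit;
* per-sample fragment sets drawn as a mixture of region-centred signal and
  uniform background, with insert sizes from a four-class mixture
  (sub-nucleosomal, mono-, di-nucleosomal, gap lengths) whose weights differ
  by platform — the default platforms reproduce the reported direction and
  fold of the platform bias (BGI-like 1.3x more sub-nucleosomal, Illumina-like
  2.6x more di-nucleosomal);
* a deliberately simple windowed Poisson-tail peak scorer standing in for an
  upstream caller, emitting overlapping narrowPeak-style candidates plus
  low-score noise peaks;
* TSS/feature annotation tying a subset of planted regions to promoters;
* negative-binomial expression tables with planted master TFs (motif
  enriched AND strongly up in the target state) and decoy motifs (enriched
  but low or flat expression).

All randomness flows from ``SimConfig.seed`` through per-purpose
``numpy.random.SeedSequence`` children, so any sample is regenerable
independently of the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .intervals import (
    FeatureInterval,
    Fragment,
    GenomicInterval,
    Peak,
    PeakSet,
    TssRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

MAX_SCORE = 1000.0  # cap for -log10 p when the tail underflows

#: Default platform insert-size mixtures (w_sub, w_mono, w_di, w_other).
#: bgi/illumina w_sub ratio = 1.3; illumina/bgi w_di ratio = 2.6.
DEFAULT_PLATFORMS = (
    ("illumina", (0.40, 0.32, 0.13, 0.15)),
    ("bgi", (0.52, 0.30, 0.05, 0.13)),
)

DEFAULT_CONDITIONS = ("mesc", "mef")

PLANTED_TFS = ("Pou5f1", "Sox2", "Klf4", "Esrrb", "Nr5a2")


@dataclass(frozen=True)
class SimConfig:
    genome: tuple = (("chr1", 12_000_000), ("chr2", 8_000_000))
    n_regions: int = 300
    region_width: int = 400
    n_replicates: int = 3
    conditions: tuple = DEFAULT_CONDITIONS
    platforms: tuple = DEFAULT_PLATFORMS
    depth: int = 30_000
    frip_target: float = 0.35
    noise_peak_rate: float = 2.0      # expected spurious peaks per Mb
    # Null rate for the window scorer, per bp.  Set above the raw background
    # fragment density (~0.001/bp at the default depth/genome) because a
    # window's overlap count sees each fragment along window + fragment
    # length, not a single bp.
    background_rate: float = 0.002
    shared_region_frac: float = 0.6   # regions accessible in both conditions
    weak_region_frac: float = 0.3    # regions drawn near the detection limit
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for label, w in self.platforms:
            w = np.asarray(w, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"platform {label!r} mixture weights must be >= 0 and sum to 1"
                )
        if not (0 < self.frip_target < 1):
            raise ValidationError("frip_target must be in (0, 1)")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        half = self.region_width // 2
        for chrom, size in self.genome:
            if size <= 2 * half:
                raise ValidationError(f"chromosome {chrom} too small for regions")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)

    @property
    def genome_length(self) -> int:
        return sum(size for _, size in self.genome)

    def samples(self) -> list[dict]:
        """Sample sheet: one entry per (condition, platform, replicate)."""
        sheet = []
        for condition in self.conditions:
            for platform, _ in self.platforms:
                for rep in range(1, self.n_replicates + 1):
                    sheet.append(
                        {
                            "sample_id": f"{condition}_{platform}_rep{rep}",
                            "condition": condition,
                            "platform": platform,
                            "replicate": rep,
                        }
                    )
        return sheet

    def platform_weights(self, platform: str) -> np.ndarray:
        for label, w in self.platforms:
            if label == platform:
                return np.asarray(w, dtype=float)
        raise ValidationError(f"unknown platform {platform!r}")


@dataclass
class PlantedRegion:
    interval: GenomicInterval
    conditions: frozenset
    strength: float

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class SyntheticTruth:
    regions: list[PlantedRegion]
    tf_truth: dict[str, dict] = field(default_factory=dict)
    mixture_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def regions_for(self, condition: str) -> list[PlantedRegion]:
        return [r for r in self.regions if condition in r.conditions]


def _rng(config: SimConfig, *tag) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 0xA7AC) + tag))


def build_truth(config: SimConfig) -> SyntheticTruth:
    """Plant non-overlapping accessible regions and TF expression effects."""
    rng = _rng(config, 1)
    half = config.region_width // 2
    sizes = np.array([s for _, s in config.genome], dtype=float)
    chrom_p = sizes / sizes.sum()

    regions: list[PlantedRegion] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in config.genome}
    attempts = 0
    while len(regions) < config.n_regions and attempts < config.n_regions * 200:
        attempts += 1
        ci = rng.choice(len(config.genome), p=chrom_p)
        chrom, size = config.genome[ci]
        center = int(rng.integers(half + 1000, size - half - 1000))
        start, end = center - half, center + half
        # keep planted regions well separated so truth intervals never overlap
        if any(start < e + 1000 and end > s - 1000 for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        u = rng.random()
        if u < config.shared_region_frac:
            conds = frozenset(config.conditions)
        else:
            k = int(rng.integers(len(config.conditions)))
            conds = frozenset([config.conditions[k]])
        if rng.random() < config.weak_region_frac:
            strength = float(rng.uniform(0.08, 0.30))
        else:
            strength = 1.0
        regions.append(
            PlantedRegion(GenomicInterval(chrom, start, end), conds, strength)
        )
    if len(regions) < config.n_regions:
        raise ValidationError("could not place planted regions; genome too crowded")

    target, background = config.conditions[0], config.conditions[1]
    tf_truth = {
        "target_condition": target,
        "background_condition": background,
        "planted": {tf: {"target_mean": 500.0, "background_mean": 1.0} for tf in PLANTED_TFS},
        "decoys_low": {f"DecoyLow{i}": {"both_mean": 2.0} for i in range(1, 6)},
        "decoys_flat": {f"DecoyFlat{i}": {"both_mean": 1000.0} for i in range(1, 11)},
    }
    mixture = {label: np.asarray(w, dtype=float) for label, w in config.platforms}
    return SyntheticTruth(regions=regions, tf_truth=tf_truth, mixture_weights=mixture)


# fragment length samplers per size class ------------------------------------

def _sample_lengths(rng: np.random.Generator, classes: np.ndarray) -> np.ndarray:
    """Class-conditional insert sizes: sub U[30,146], mono N(200,20) on
    [180,247], di N(400,30) on [315,473], other uniform on the gap ranges."""
    n = len(classes)
    lengths = np.zeros(n, dtype=np.int64)

    sub = classes == 0
    lengths[sub] = rng.integers(30, 147, size=int(sub.sum()))

    for code, mu, sd, lo, hi in ((1, 200.0, 20.0, 180, 247), (2, 400.0, 30.0, 315, 473)):
        mask = classes == code
        m = int(mask.sum())
        if m == 0:
            continue
        vals = np.rint(rng.normal(mu, sd, size=m)).astype(np.int64)
        bad = (vals < lo) | (vals > hi)
        while bad.any():
            vals[bad] = np.rint(rng.normal(mu, sd, size=int(bad.sum()))).astype(np.int64)
            bad = (vals < lo) | (vals > hi)
        lengths[mask] = vals

    other = classes == 3
    m = int(other.sum())
    if m:
        # gaps: 147-179, 248-314, 474-600
        pools = [(147, 180), (248, 315), (474, 601)]
        widths = np.array([b - a for a, b in pools], dtype=float)
        pick = rng.choice(3, size=m, p=widths / widths.sum())
        vals = np.empty(m, dtype=np.int64)
        for j, (a, b) in enumerate(pools):
            sel = pick == j
            vals[sel] = rng.integers(a, b, size=int(sel.sum()))
        lengths[other] = vals
    return lengths


def simulate_fragments(
    config: SimConfig, sample_index: int, truth: SyntheticTruth | None = None
) -> tuple[list[Fragment], SyntheticTruth]:
    """Fragment set for one sample of the sample sheet.

    With probability ``frip_target`` a fragment centre is drawn near a
    planted region centre (Gaussian, sd = region_width/4, regions weighted
    by strength); otherwise uniformly on the genome.  Lengths follow the
    sample's platform mixture.  Reproducible per (seed, sample_index).
    """
    sheet = config.samples()
    if not (0 <= sample_index < len(sheet)):
        raise ValidationError(f"sample_index {sample_index} out of range")
    sample = sheet[sample_index]
    if truth is None:
        truth = build_truth(config)

    rng = _rng(config, 2, sample_index)
    n = config.depth
    weights = config.platform_weights(sample["platform"])
    regions = truth.regions_for(sample["condition"])
    strengths = np.array([r.strength for r in regions], dtype=float)
    region_p = strengths / strengths.sum()
    centers = np.array([r.center for r in regions], dtype=np.int64)
    region_chrom = np.array([r.interval.chrom for r in regions])

    sizes = np.array([s for _, s in config.genome], dtype=np.int64)
    chrom_names = np.array([c for c, _ in config.genome])
    chrom_p = sizes / sizes.sum()

    is_signal = rng.random(n) < config.frip_target
    classes = rng.choice(4, size=n, p=weights)
    lengths = _sample_lengths(rng, classes)

    chroms = np.empty(n, dtype=object)
    frag_centers = np.empty(n, dtype=np.int64)

    n_sig = int(is_signal.sum())
    if n_sig:
        ridx = rng.choice(len(regions), size=n_sig, p=region_p)
        offsets = rng.normal(0.0, config.region_width / 4.0, size=n_sig)
        frag_centers[is_signal] = centers[ridx] + np.rint(offsets).astype(np.int64)
        chroms[is_signal] = region_chrom[ridx]

    n_bg = n - n_sig
    if n_bg:
        ci = rng.choice(len(sizes), size=n_bg, p=chrom_p)
        pos = (rng.random(n_bg) * sizes[ci]).astype(np.int64)
        frag_centers[~is_signal] = pos
        chroms[~is_signal] = chrom_names[ci]

    size_lookup = config.chrom_sizes
    starts = frag_centers - lengths // 2
    fragments: list[Fragment] = []
    for i in range(n):
        chrom = chroms[i]
        limit = size_lookup[chrom]
        s = int(starts[i])
        e = s + int(lengths[i])
        if s < 0:  # shift inside the chromosome, preserving length
            e -= s
            s = 0
        if e > limit:
            s -= e - limit
            e = limit
            s = max(s, 0)
        fragments.append(Fragment(GenomicInterval(chrom, s, e)))
    return fragments, truth


def poisson_tail_score(k: int, mu: float) -> float:
    """-log10 P(X >= k) for X ~ Poisson(mu); 0 for k = 0, capped at 1000."""
    if k <= 0:
        return 0.0
    logsf = poisson.logsf(k - 1, mu)
    if not np.isfinite(logsf):
        return MAX_SCORE
    return float(min(MAX_SCORE, -logsf / math.log(10)))


def simulate_peak_calls(
    fragments: Sequence[Fragment],
    config: SimConfig,
    sample_id: str = "sample",
    sample_index: int = 0,
    window: int = 501,
    step: int = 100,
    min_score: float = 2.0,
) -> PeakSet:
    """Windowed Poisson-tail peak caller plus injected low-score noise peaks.

    Windows of ``window`` bp stepped by ``step`` bp are scored as
    -log10 P(X >= k) with X ~ Poisson(background_rate * window), where k is
    the number of overlapping fragments.  Windows scoring above ``min_score``
    become candidate peaks with the summit at the window's coverage argmax.
    The output deliberately contains overlapping candidates.
    """
    rng = _rng(config, 3, sample_index)
    mu = config.background_rate * window
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)

    # precompute tail scores for the small counts we will actually see
    peaks: list[Peak] = []
    score_cache: dict[int, float] = {}

    for chrom, size in config.genome:
        frs = by_chrom.get(chrom, [])
        if not frs:
            continue
        raw_starts = np.array([f.start for f in frs], dtype=np.int64)
        raw_ends = np.array([f.end for f in frs], dtype=np.int64)
        starts = np.sort(raw_starts)
        ends = np.sort(raw_ends)
        cov = np.zeros(size + 1, dtype=np.int32)
        np.add.at(cov, raw_starts, 1)
        np.add.at(cov, raw_ends, -1)
        cov = np.cumsum(cov[:-1], dtype=np.int32)

        w = np.arange(0, size - window + 1, step, dtype=np.int64)
        k = np.searchsorted(starts, w + window, side="left") - np.searchsorted(
            ends, w, side="right"
        )
        # map counts to tail scores through a per-unique-count cache
        uniq = np.unique(k)
        for ki in uniq:
            if int(ki) not in score_cache:
                score_cache[int(ki)] = poisson_tail_score(int(ki), mu)
        scores = np.array([score_cache[int(ki)] for ki in uniq])
        window_scores = scores[np.searchsorted(uniq, k)]
        hits = window_scores > min_score
        for wi, ki, score in zip(w[hits], k[hits], window_scores[hits]):
            ki = int(ki)
            score = float(score)
            summit = int(wi + np.argmax(cov[wi : wi + window]))
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, int(wi), int(wi + window)),
                    summit=summit,
                    score=score,
                    sample_id=sample_id,
                    name=f"{sample_id}_w{wi}",
                    signal=float(ki),
                )
            )

    # noise peaks: spurious low-score calls at random positions
    n_noise = rng.poisson(config.noise_peak_rate * config.genome_length / 1e6)
    sizes = np.array([s for _, s in config.genome], dtype=np.int64)
    chrom_p = sizes / sizes.sum()
    half = window // 2
    for j in range(int(n_noise)):
        ci = int(rng.choice(len(sizes), p=chrom_p))
        chrom, size = config.genome[ci]
        center = int(rng.integers(half, size - half))
        score = float(rng.uniform(2.0, 4.0))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, center - half, center - half + window),
                summit=center,
                score=score,
                sample_id=sample_id,
                name=f"{sample_id}_noise{j}",
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(sample_id=sample_id, peaks=peaks)


def simulate_annotation(
    config: SimConfig, truth: SyntheticTruth, n_random_tss: int = 100
) -> tuple[list[TssRecord], list[FeatureInterval]]:
    """TSS records and gene-model feature intervals.

    Every other planted region receives a TSS at its centre (making it
    promoter-proximal); additional TSSs land at random positions.  Each gene
    contributes promoter (TSS +/- 1 kb), then strand-ordered utr5 / exon /
    intron / exon / utr3 blocks.
    """
    rng = _rng(config, 4)
    size_lookup = config.chrom_sizes
    tss: list[TssRecord] = []
    for i, region in enumerate(truth.regions):
        if i % 2 == 0:
            strand = "+" if i % 4 == 0 else "-"
            tss.append(TssRecord(f"regiongene_{i}", region.interval.chrom, region.center, strand))
    sizes = np.array([s for _, s in config.genome], dtype=np.int64)
    chrom_p = sizes / sizes.sum()
    for j in range(n_random_tss):
        ci = int(rng.choice(len(sizes), p=chrom_p))
        chrom, size = config.genome[ci]
        pos = int(rng.integers(5000, size - 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TssRecord(f"randgene_{j}", chrom, pos, strand))

    features: list[FeatureInterval] = []
    blocks = (("utr5", 200), ("exon", 300), ("intron", 500), ("exon", 300), ("utr3", 300))
    for t in tss:
        limit = size_lookup[t.chrom]
        p_start = max(0, t.pos - 1000)
        p_end = min(limit, t.pos + 1001)
        features.append(FeatureInterval(GenomicInterval(t.chrom, p_start, p_end), "promoter"))
        cursor = t.pos + 1001 if t.strand == "+" else t.pos - 1001
        for label, width in blocks:
            if t.strand == "+":
                s, e = cursor, cursor + width
                cursor = e
            else:
                s, e = cursor - width, cursor
                cursor = s
            if s < 0 or e > limit:
                break
            features.append(FeatureInterval(GenomicInterval(t.chrom, s, e), label))
    return tss, features


def simulate_blacklist(config: SimConfig, truth: SyntheticTruth, n: int = 5) -> list[GenomicInterval]:
    """A few decoy high-signal regions to be excluded from peak sets."""
    from .intervals import IntervalIndex

    rng = _rng(config, 5)
    planted = IntervalIndex((r.interval, r) for r in truth.regions)
    out: list[GenomicInterval] = []
    sizes = np.array([s for _, s in config.genome], dtype=np.int64)
    chrom_p = sizes / sizes.sum()
    while len(out) < n:
        ci = int(rng.choice(len(sizes), p=chrom_p))
        chrom, size = config.genome[ci]
        start = int(rng.integers(0, size - 1000))
        if planted.any_overlap(GenomicInterval(chrom, start, start + 1000)):
            continue
        out.append(GenomicInterval(chrom, start, start + 1000))
    return out


def simulate_expression(
    config: SimConfig, truth: SyntheticTruth, n_background_genes: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Expression counts, motif enrichment table, and sample->condition map.

    Counts are negative binomial (dispersion ``nb_dispersion``) around
    per-condition means.  Planted master TFs are high in the target
    condition and near zero in the background; low decoys sit below the
    robust-expression floor in both; flat decoys are high in both.  The
    motif table lists planted motifs first (smallest FDR), then decoys,
    then filler motifs, in ascending FDR order.
    """
    rng = _rng(config, 6)
    tf = truth.tf_truth
    target, background = tf["target_condition"], tf["background_condition"]

    genes: list[str] = []
    means = {target: [], background: []}
    for name, eff in tf["planted"].items():
        genes.append(name)
        means[target].append(eff["target_mean"])
        means[background].append(eff["background_mean"])
    for name, eff in tf["decoys_low"].items():
        genes.append(name)
        means[target].append(eff["both_mean"])
        means[background].append(eff["both_mean"])
    for name, eff in tf["decoys_flat"].items():
        genes.append(name)
        means[target].append(eff["both_mean"])
        means[background].append(eff["both_mean"])
    bg_means = rng.lognormal(mean=np.log(1500.0), sigma=1.0, size=n_background_genes)
    for i, m in enumerate(bg_means):
        genes.append(f"Gene{i}")
        means[target].append(float(m))
        means[background].append(float(m))

    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    data = {}
    conditions = {}
    for cond in (target, background):
        mu = np.asarray(means[cond], dtype=float)
        mu = np.maximum(mu, 1e-8)
        p = nb_n / (nb_n + mu)
        for rep in range(1, config.n_replicates + 1):
            col = f"{cond}_rna_rep{rep}"
            data[col] = rng.negative_binomial(nb_n, p)
            conditions[col] = cond
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))

    motif_rows = []
    fdr = 1e-50
    for name in tf["planted"]:
        motif_rows.append((f"motif_{name}", name, fdr / 10, fdr))
        fdr *= 10
    fdr = 1e-30
    for name in list(tf["decoys_low"]) + list(tf["decoys_flat"]):
        motif_rows.append((f"motif_{name}", name, fdr / 10, fdr))
        fdr *= 2
    for i in range(10):  # filler motifs beyond the informative ones
        gene = f"Gene{i}"
        motif_rows.append((f"motif_filler{i}", gene, 1e-6 * (i + 1), 1e-5 * (i + 1)))
    motifs = pd.DataFrame(motif_rows, columns=["motif_id", "tf_gene", "p_value", "fdr"])
    return counts, motifs, conditions
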