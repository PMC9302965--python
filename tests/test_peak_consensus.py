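import numpy as np
import pytest

from atacpeaks.intervals import GenomicInterval, PeakSet, ValidationError
from atacpeaks.peak_consensus import (
    SPM_TOTAL,
    ConsensusParams,
    filter_blacklist,
    iterative_removal,
    merge_consensus_sets,
    renormalize_spm,
    replicate_consensus,
    spm_normalize,
    spm_normalize_peakset,
    to_fixed_width,
)

from conftest import mk_peak

CHROM_SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def naive_iterative_removal(peaks, score_of=lambda p: p.score):
    """Independent oracle: literal repeated keep-best-discard-overlaps scan."""
    remaining = list(peaks)
    kept = []
    while remaining:
        best = min(
            remaining,
            key=lambda p: (-score_of(p), p.chrom, p.start, p.sample_id),
        )
        kept.append(best)
        remaining = [
            p for p in remaining
            if p is not best and not p.interval.overlaps(best.interval)
        ]
    return sorted(kept, key=lambda p: (p.chrom, p.start))


def random_instance(rng, n_max=12):
    n = int(rng.integers(1, n_max + 1))
    peaks = []
    for i in range(n):
        chrom = "chr1" if rng.random() < 0.8 else "chr2"
        start = int(rng.integers(0, 2000))
        width = int(rng.integers(50, 600))
        score = float(rng.integers(1, 6))  # small range to provoke ties
        peaks.append(
            mk_peak(chrom=chrom, start=start, end=start + width,
                    score=score, sample_id=f"s{i % 3}")
        )
    return peaks


# --- fixed-width conversion ---------------------------------------------------

def test_fixed_width_definition():
    ps = PeakSet("s1", [mk_peak(start=9000, end=11001, summit=10_000)])
    out = to_fixed_width(ps, CHROM_SIZES)
    (p,) = out.peaks
    assert (p.start, p.end) == (9750, 10251)
    assert p.width == 501


def test_fixed_width_drops_boundary_peaks():
    ps = PeakSet("s1", [mk_peak(start=0, end=501, summit=100)])
    assert len(to_fixed_width(ps, CHROM_SIZES)) == 0
    near_end = PeakSet("s1", [mk_peak(start=999_400, end=999_901, summit=999_900)])
    assert len(to_fixed_width(near_end, CHROM_SIZES)) == 0
    assert len(to_fixed_width(PeakSet("s1", []), CHROM_SIZES)) == 0


# --- blacklist ----------------------------------------------------------------

def test_blacklist_one_bp_rule():
    inside = mk_peak(start=1000, end=1501, summit=1250)
    grazing = mk_peak(start=1999, end=2500, summit=2200)  # 1 bp into [0,2000)
    clear = mk_peak(start=3000, end=3501, summit=3250)
    ps = PeakSet("s1", [inside, grazing, clear])
    bl = [GenomicInterval("chr1", 0, 2000)]
    assert [p.start for p in filter_blacklist(ps, bl)] == [3000]
    assert len(filter_blacklist(ps, [])) == 3


# --- iterative removal --------------------------------------------------------

def test_iterative_removal_worked_examples():
    a = mk_peak(start=0, end=501, score=10)
    b = mk_peak(start=250, end=751, score=20)
    c = mk_peak(start=600, end=1101, score=5)
    out = iterative_removal(PeakSet("s1", [a, b, c]))
    assert [p.start for p in out] == [250]  # only B: A and C both overlap it

    a = mk_peak(start=0, end=501, score=30)
    b = mk_peak(start=400, end=901, score=25)
    c = mk_peak(start=800, end=1301, score=20)
    out = iterative_removal(PeakSet("s1", [a, b, c]))
    assert [p.start for p in out] == [0, 800]  # B removed by A, C survives


def test_iterative_removal_identity_on_disjoint(small_peakset):
    out = iterative_removal(small_peakset)
    assert [p.start for p in out] == [0, 1000, 3000]


def test_iterative_removal_deterministic_tie_break():
    a = mk_peak(start=100, end=601, score=5, sample_id="s2")
    b = mk_peak(start=100, end=601, score=5, sample_id="s1")
    out = iterative_removal(PeakSet("x", [a, b]))
    assert len(out) == 1 and out.peaks[0].sample_id == "s1"


def test_iterative_removal_matches_oracle_and_idempotent():
    rng = np.random.default_rng(42)
    for _ in range(200):
        peaks = random_instance(rng)
        ps = PeakSet("x", peaks)
        got = iterative_removal(ps)
        expected = naive_iterative_removal(peaks)
        assert got.peaks == expected
        assert iterative_removal(got).peaks == got.peaks


# --- SPM ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "scores,expected",
    [
        ([10], [1_000_000]),
        ([10, 10], [500_000, 500_000]),
        ([10, 30, 60], [100_000, 300_000, 600_000]),
    ],
)
def test_spm_worked_examples(scores, expected):
    assert spm_normalize(scores) == pytest.approx(expected, rel=1e-12)


def test_spm_conservation_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        scores = rng.random(int(rng.integers(1, 200))) * 100
        spm = spm_normalize(scores)
        assert abs(spm.sum() - SPM_TOTAL) <= 1e-9 * SPM_TOTAL


def test_spm_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        spm_normalize([0.0, 0.0])
    with pytest.raises(ValidationError):
        spm_normalize([-1.0, 2.0])


# --- replicate consensus ------------------------------------------------------

def _sample(sample_id, *peaks):
    return spm_normalize_peakset(PeakSet(sample_id, list(peaks)))


def _raw_samples(locus_scores):
    """Build SPM-carrying samples from {sample: [(start, spm), ...]}.

    SPM values are planted directly (no normalization) so reproducibility
    rules can be tested against exact thresholds.
    """
    out = []
    for sid, entries in locus_scores.items():
        peaks = [
            mk_peak(start=s, end=s + 501, score=spm, spm=spm, sample_id=sid)
            for s, spm in entries
        ]
        out.append(PeakSet(sid, peaks))
    return out


def test_replicate_consensus_support_rules():
    # same locus in 2 of 3 samples, spm {5, 4} -> kept with support 2
    samples = _raw_samples({"s1": [(1000, 5.0)], "s2": [(1000, 4.0)], "s3": []})
    out = replicate_consensus(samples, label="c")
    assert len(out) == 1 and out.peaks[0].support == 2

    # spm {5, 2.9}: only one sample qualifies -> dropped
    samples = _raw_samples({"s1": [(1000, 5.0)], "s2": [(1000, 2.9)], "s3": []})
    assert len(replicate_consensus(samples)) == 0

    # single very strong sample -> dropped (support 1 < 2)
    samples = _raw_samples({"s1": [(1000, 50.0)], "s2": [], "s3": []})
    assert len(replicate_consensus(samples)) == 0


def test_replicate_consensus_fifty_percent_overlap():
    # offset 250 -> intersection 251 bp = ceil(0.5 * 501): qualifies
    samples = _raw_samples({"s1": [(1000, 5.0)], "s2": [(1250, 4.0)]})
    assert len(replicate_consensus(samples)) == 1
    # offset 251 -> intersection 250 bp: support fails
    samples = _raw_samples({"s1": [(1000, 5.0)], "s2": [(1251, 4.0)]})
    assert len(replicate_consensus(samples)) == 0


def test_replicate_consensus_requires_min_samples():
    with pytest.raises(ValidationError):
        replicate_consensus(_raw_samples({"s1": [(0, 5.0)]}))


def test_replicate_consensus_permutation_invariant():
    rng = np.random.default_rng(3)
    samples = []
    for sid in ("s1", "s2", "s3"):
        peaks = []
        for start in rng.integers(0, 50_000, size=20):
            start = int(start)
            peaks.append(mk_peak(start=start, end=start + 501,
                                 score=float(rng.integers(1, 100)), sample_id=sid))
        samples.append(spm_normalize_peakset(iterative_removal(PeakSet(sid, peaks))))
    ref = replicate_consensus(samples, label="c")
    perm = replicate_consensus([samples[2], samples[0], samples[1]], label="c")
    assert [(cp.interval.start, cp.support) for cp in ref] == [
        (cp.interval.start, cp.support) for cp in perm
    ]


# --- cross-set merge ----------------------------------------------------------

def _consensus_of(label, *entries):
    samples = _raw_samples({f"{label}_r1": list(entries), f"{label}_r2": list(entries)})
    return replicate_consensus(samples, label=label)


def test_merge_identical_sets():
    a = _consensus_of("a", (1000, 5.0))
    b = _consensus_of("b", (1000, 7.0))
    merged = merge_consensus_sets([a, b])
    assert len(merged) == 1
    assert merged.peaks[0].sources == {"a", "b"}


def test_merge_disjoint_sets():
    a = _consensus_of("a", (1000, 5.0))
    b = _consensus_of("b", (9000, 7.0))
    merged = merge_consensus_sets([a, b])
    assert len(merged) == 2
    assert sorted(next(iter(cp.sources)) for cp in merged) == ["a", "b"]


def test_merge_renormalizes_spm_per_set():
    a = _consensus_of("a", (1000, 5.0), (9000, 5.0))
    b = _consensus_of("b", (1000, 200.0), (9000, 600.0))
    merged = merge_consensus_sets([a, b])
    # after per-set renormalization both a-peaks carry 500k; b carries 250k/750k
    spm_by_locus = {cp.interval.start: (cp.spm, cp.peak.sample_id) for cp in merged}
    assert spm_by_locus[1000][0] == pytest.approx(500_000.0, rel=1e-12)
    assert spm_by_locus[1000][1] == "a"
    assert spm_by_locus[9000][0] == pytest.approx(750_000.0, rel=1e-12)
    assert spm_by_locus[9000][1] == "b"
    assert all(cp.sources == {"a", "b"} for cp in merged)


def test_renormalize_empty_set_rejected():
    from atacpeaks.peak_consensus import ConsensusPeakSet
    with pytest.raises(ValidationError):
        renormalize_spm(ConsensusPeakSet(label="x"))
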