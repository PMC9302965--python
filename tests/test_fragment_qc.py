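import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atacpeaks.fragment_qc import (
    SIZE_CLASSES,
    SizeClassScheme,
    classify_fragment_length,
    count_in_peaks,
    frip,
    frot,
    size_distribution,
    subsample_fragments,
    tss_profile,
)
from atacpeaks.intervals import Fragment, GenomicInterval, PeakSet, TssRecord, ValidationError
from atacpeaks.synthetic import SimConfig, build_truth, simulate_fragments

from conftest import mk_fragment, mk_peak


@pytest.mark.parametrize(
    "length,expected",
    [
        (100, "sub"),
        (146, "sub"),
        (147, "other"),   # gap between sub and mono
        (150, "other"),
        (180, "mono"),
        (200, "mono"),
        (247, "mono"),
        (248, "other"),
        (315, "di"),
        (400, "di"),
        (473, "di"),
        (474, "other"),
    ],
)
def test_classify_fragment_length(length, expected):
    assert classify_fragment_length(length) == expected


def test_classify_rejects_nonpositive_length():
    with pytest.raises(ValidationError):
        classify_fragment_length(0)


@given(st.integers(min_value=1, max_value=2000))
def test_every_length_gets_exactly_one_class(length):
    assert classify_fragment_length(length) in SIZE_CLASSES


def test_size_distribution_counting():
    frags = [mk_fragment(end=n) for n in (100, 100, 200, 400)]
    hist, props = size_distribution(frags)
    assert props == {"sub": 0.5, "mono": 0.25, "di": 0.25, "other": 0.0}
    assert hist == {100: 2, 200: 1, 400: 1}


def test_size_distribution_degenerate_cases():
    _, props = size_distribution([mk_fragment(end=200)] * 3)
    assert props["mono"] == 1.0
    _, props = size_distribution([mk_fragment(end=150)])
    assert props["other"] == 1.0
    with pytest.raises(ValidationError):
        size_distribution([])


@given(st.lists(st.integers(min_value=1, max_value=800), min_size=1, max_size=50))
def test_size_proportions_partition(lengths):
    frags = [Fragment(GenomicInterval("chr1", 0, n)) for n in lengths]
    _, props = size_distribution(frags)
    assert abs(sum(props.values()) - 1.0) < 1e-9
    assert all(0 <= v <= 1 for v in props.values())


TSS = [TssRecord("g1", "chr1", 1500, "+")]


def test_frot_interval_intersection():
    assert frot([mk_fragment(start=900, end=1000)], TSS, window=1000) == 1.0
    assert frot([mk_fragment(start=5000, end=5100)], TSS, window=1000) == 0.0
    both = [mk_fragment(start=900, end=1000), mk_fragment(start=5000, end=5100)]
    assert frot(both, TSS, window=1000) == 0.5


def test_frot_empty_tss_warns_and_returns_zero(caplog):
    assert frot([mk_fragment()], [], window=1000) == 0.0


def test_frot_monotone_in_tss_records():
    frags = [mk_fragment(start=i * 3000, end=i * 3000 + 100) for i in range(10)]
    tss = []
    last = 0.0
    for i in range(5):
        tss.append(TssRecord(f"g{i}", "chr1", i * 3000 + 50, "+"))
        cur = frot(frags, tss)
        assert cur >= last
        last = cur


def test_tss_profile_shape_and_placement():
    prof = tss_profile([], TSS, window=1000, bin=10)
    assert len(prof) == 200 and not prof.any()
    # a fragment exactly covering the first bin downstream of the TSS
    frag = mk_fragment(start=1500, end=1510)
    prof = tss_profile([frag], TSS, window=1000, bin=10)
    assert prof[100] == 1.0
    assert np.count_nonzero(prof) == 1


def test_tss_profile_minus_strand_reversed():
    tss_minus = [TssRecord("g1", "chr1", 1500, "-")]
    frag = mk_fragment(start=1500, end=1510)  # downstream on + coords
    prof = tss_profile([frag], tss_minus, window=1000, bin=10)
    assert prof[99] == 1.0  # reversed into the upstream half


def test_tss_profile_window_bin_divisibility():
    with pytest.raises(ValidationError):
        tss_profile([], TSS, window=1000, bin=3)


def test_frip_three_way_partition():
    peaks = PeakSet("s1", [
        mk_peak(start=1000, end=1501, summit=1250),   # proximal (TSS 1500)
        mk_peak(start=50000, end=50501, summit=50250),  # distal
    ])
    frags = [
        mk_fragment(start=1200, end=1300),     # in proximal peak
        mk_fragment(start=50100, end=50200),   # in distal peak
        mk_fragment(start=80000, end=80100),
        mk_fragment(start=90000, end=90100),
    ]
    result = frip(frags, peaks, TSS, window=1000)
    assert result == {"tss_peaks": 0.25, "distal_peaks": 0.25, "not_in_peaks": 0.5}
    assert abs(sum(result.values()) - 1.0) < 1e-9


def test_frip_proximal_precedence():
    """A fragment under both a proximal and a distal peak counts as proximal."""
    peaks = PeakSet("s1", [
        mk_peak(start=1000, end=1501, summit=1250),
        mk_peak(start=1501, end=2002, summit=1750),  # distal, adjacent
    ])
    tss = [TssRecord("g1", "chr1", 500, "+")]  # only first peak proximal
    frag = [mk_fragment(start=1400, end=1600)]  # spans both peaks
    result = frip(frag, peaks, tss, window=1000)
    assert result["tss_peaks"] == 1.0


def test_count_in_peaks_rules():
    peaks = PeakSet("c", [
        mk_peak(start=1000, end=1501, summit=1250),
        mk_peak(start=3000, end=3501, summit=3250),
    ])
    frags = [mk_fragment(start=1100, end=1200)] * 3 + [
        mk_fragment(start=900, end=1001)  # 1 bp inside the first peak
    ]
    assert count_in_peaks(frags, peaks).tolist() == [4, 0]
    assert count_in_peaks([], peaks).tolist() == [0, 0]


def test_count_in_peaks_rejects_overlapping_peaks():
    peaks = PeakSet("c", [
        mk_peak(start=1000, end=1501, summit=1250),
        mk_peak(start=1400, end=1901, summit=1650),
    ])
    with pytest.raises(ValidationError):
        count_in_peaks([], peaks)


def test_subsample_contracts():
    frags = [mk_fragment(start=i, end=i + 100) for i in range(50)]
    assert subsample_fragments(frags, 50, seed=1) == frags
    assert subsample_fragments(frags, 0, seed=1) == []
    a = subsample_fragments(frags, 20, seed=7)
    b = subsample_fragments(frags, 20, seed=7)
    assert a == b
    with pytest.raises(ValidationError):
        subsample_fragments(frags, 51, seed=1)


def test_subsample_preserves_class_proportions_in_expectation():
    """Mean subsampled class proportions across seeds match the full set."""
    cfg = SimConfig(depth=2000, seed=5)
    frags, _ = simulate_fragments(cfg, 0)
    _, full = size_distribution(frags)
    n = 500
    means = {c: 0.0 for c in SIZE_CLASSES}
    n_seeds = 100
    for seed in range(n_seeds):
        _, props = size_distribution(subsample_fragments(frags, n, seed=seed))
        for c in SIZE_CLASSES:
            means[c] += props[c] / n_seeds
    for c in SIZE_CLASSES:
        se = np.sqrt(full[c] * (1 - full[c]) / n) / np.sqrt(n_seeds)
        assert abs(means[c] - full[c]) <= 3 * max(se, 1e-12) + 1e-9
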