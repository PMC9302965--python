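import pytest
from hypothesis import HealthCheck, settings

from atacpeaks.intervals import Fragment, GenomicInterval, Peak, PeakSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mk_peak(chrom="chr1", start=0, end=501, summit=None, score=1.0,
            sample_id="s1", spm=None, name="."):
    if summit is None:
        summit = (start + end) // 2
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        score=score,
        spm=spm,
        sample_id=sample_id,
        name=name,
    )


def mk_fragment(chrom="chr1", start=0, end=100):
    return Fragment(GenomicInterval(chrom, start, end))


@pytest.fixture
def peak_factory():
    return mk_peak


@pytest.fixture
def fragment_factory():
    return mk_fragment


@pytest.fixture
def small_peakset():
    return PeakSet(
        sample_id="s1",
        peaks=[
            mk_peak(start=0, end=501, summit=250, score=10.0),
            mk_peak(start=1000, end=1501, summit=1250, score=30.0),
            mk_peak(start=3000, end=3501, summit=3250, score=60.0),
        ],
    )
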