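"""Truth-aware evaluation of pipeline output on synthetic studies."""

from __future__ import annotations

from typing import Mapping, Sequence

from .intervals import Fragment, IntervalIndex, PeakSet
from .peak_consensus import ConsensusParams, ConsensusPeakSet
from .pipeline import build_consensus
from .synthetic import (
    SimConfig,
    SyntheticTruth,
    build_truth,
    simulate_fragments,
    simulate_peak_calls,
)


def simulate_condition(
    config: SimConfig,
    condition: str,
    truth: SyntheticTruth | None = None,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[dict[str, ConsensusPeakSet], dict[str, list[Fragment]], SyntheticTruth]:
    """Simulate all samples of one condition and build per-platform consensus."""
    if truth is None:
        truth = build_truth(config)
    by_platform: dict[str, list[PeakSet]] = {}
    fragments: dict[str, list[Fragment]] = {}
    for i, sample in enumerate(config.samples()):
        if sample["condition"] != condition:
            continue
        frags, _ = simulate_fragments(config, i, truth)
        fragments[sample["sample_id"]] = frags
        calls = simulate_peak_calls(frags, config, sample["sample_id"], i)
        by_platform.setdefault(sample["platform"], []).append(calls)
    consensus = {
        platform: build_consensus(
            sets, config.chrom_sizes, [], params, label=f"{condition}_{platform}"
        )[0]
        for platform, sets in by_platform.items()
    }
    return consensus, fragments, truth


def planted_recovery(
    consensus: ConsensusPeakSet,
    truth: SyntheticTruth,
    condition: str,
    min_frac: float = 0.5,
) -> tuple[float, float]:
    """(fraction of planted regions recovered, fraction of spurious peaks).

    A planted region counts as recovered when a consensus peak overlaps it by
    >= min_frac of the region's length; a consensus peak is spurious when it
    overlaps no planted region at all (>= 1 bp, any condition).
    """
    regions = truth.regions_for(condition)
    peak_idx = IntervalIndex((cp.interval, cp) for cp in consensus)
    recovered = sum(
        1
        for r in regions
        if any(
            cp.interval.overlap_bp(r.interval) >= min_frac * len(r.interval)
            for cp in peak_idx.overlapping(r.interval)
        )
    )
    truth_idx = IntervalIndex((r.interval, r) for r in truth.regions)
    spurious = sum(1 for cp in consensus if not truth_idx.any_overlap(cp.interval))
    return recovered / len(regions), spurious / max(1, len(consensus))
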