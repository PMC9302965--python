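"""High-level stage orchestration shared by the CLI, the analysis drivers,
and the acceptance checks."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .fragment_qc import count_in_peaks
from .intervals import GenomicInterval, PeakSet
from .peak_consensus import (
    ConsensusParams,
    ConsensusPeakSet,
    filter_blacklist,
    iterative_removal,
    replicate_consensus,
    spm_normalize_peakset,
    to_fixed_width,
)

log = logging.getLogger(__name__)


def prepare_sample(
    peakset: PeakSet,
    chrom_sizes: dict[str, int],
    blacklist: Sequence[GenomicInterval] = (),
    params: ConsensusParams = ConsensusParams(),
) -> tuple[PeakSet, dict[str, int]]:
    """Per-sample preprocessing: fixed-width -> blacklist -> iterative
    removal -> SPM normalization.  Returns the prepared set and per-stage
    record counts for the run manifest."""
    counts = {"input": len(peakset)}
    ps = to_fixed_width(peakset, chrom_sizes, params.extension)
    counts["fixed_width"] = len(ps)
    ps = filter_blacklist(ps, blacklist)
    counts["blacklist_filtered"] = len(ps)
    ps = iterative_removal(ps)
    counts["after_iterative_removal"] = len(ps)
    ps = spm_normalize_peakset(ps)
    counts["spm_normalized"] = len(ps)
    return ps, counts


def build_consensus(
    peaksets: Sequence[PeakSet],
    chrom_sizes: dict[str, int],
    blacklist: Sequence[GenomicInterval] = (),
    params: ConsensusParams = ConsensusParams(),
    label: str = "consensus",
) -> tuple[ConsensusPeakSet, dict]:
    """Full per-set workflow: prepare each replicate, then the
    reproducibility consensus."""
    prepared = []
    stage_counts = {}
    for ps in peaksets:
        prep, counts = prepare_sample(ps, chrom_sizes, blacklist, params)
        prepared.append(prep)
        stage_counts[ps.sample_id] = counts
    consensus = replicate_consensus(prepared, params, label=label)
    stage_counts["consensus"] = {"reproducible_peaks": len(consensus)}
    return consensus, stage_counts


def counts_table(
    consensus: ConsensusPeakSet, fragments_by_sample: Mapping[str, Sequence]
) -> pd.DataFrame:
    """Peak-by-sample fragment count matrix over a consensus peak set."""
    peak_ids = [
        f"{cp.interval.chrom}:{cp.interval.start}-{cp.interval.end}"
        for cp in consensus
    ]
    data = {
        sample: count_in_peaks(frags, consensus.as_peakset())
        for sample, frags in fragments_by_sample.items()
    }
    return pd.DataFrame(data, index=pd.Index(peak_ids, name="id"))
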