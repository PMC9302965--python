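# atacpeaks

Analysis pipeline for comparing ATAC-seq libraries across sequencing
platforms and cell states: fragment-size and signal-to-background QC,
fixed-width reproducible consensus peak sets with score-per-million
normalization, shared vs platform-specific peak accounting, and
motif-enrichment × expression integration for master-TF nomination. It is
aimed at epigenomics analysts who already have per-sample peak calls
(ENCODE narrowPeak) and fragment intervals (BED) and need the downstream
consensus/comparison layer as tested, reusable code.

## The core procedure

For each sample, peak summits are extended ±250 bp into 501 bp fixed-width
peaks, blacklist-overlapping peaks are removed, and within-sample overlaps
are resolved by **iterative removal** (repeatedly keep the most significant
remaining peak, discard everything overlapping it). Scores — the caller's
−log10 p-values — are normalized to **score per million**:

    spm_i = score_i / (Σ_j score_j / 10^6)

so each sample's SPM vector sums to 10^6 and scores are comparable across
libraries of different depth/quality. A **replicate consensus** pools all
samples, reruns iterative removal ranked by SPM, and keeps peaks with
SPM ≥ 3 observed in ≥ 2 samples at ≥ 50 % overlap of the fixed width.
Consensus sets are compared by re-normalizing each set's SPM to 10^6,
pooling, rerunning iterative removal, and classifying each surviving peak as
shared or set-specific from which inputs contributed a ≥ 50 %-overlapping
peak.

QC statistics follow the standard nucleosomal insert-size classes
(sub < 147 bp, mono 180–247 bp, di 315–473 bp), FROT (fraction of fragments
within ±1 kb of a TSS) and a three-way FRiP split (TSS-proximal peaks /
distal peaks / not in peaks). TF nomination takes the top-25 non-redundant
enriched motifs, keeps TFs expressed > 2 log2CPM in the target cell state,
and re-ranks them by the cross-state log2CPM difference.

A synthetic-data module generates a complete two-cell-type, two-platform,
three-replicate study with ground truth (planted accessible regions,
platform-specific insert-size mixtures, planted master TFs and decoy
motifs), so the whole pipeline is testable without any downloads. See
`docs/methods.md` for the model and all defaults.

## Worked example

Run the numbered drivers (each is a thin script over the library and writes
its tables under `results/`):

```sh
python analysis/01_simulate.py --seed 1      # synthetic study -> results/sim/
python analysis/02_fragment_qc.py            # QC per sample
python analysis/03_consensus_peaks.py        # consensus sets + count matrix
python analysis/04_platform_comparison.py    # shared/specific accounting
python analysis/05_motif_expression.py       # master-TF nomination
```

With seed 1 the QC driver ends with

```
BGI/Illumina sub-nucleosomal fold: 1.30 (generator plants 1.3)
Illumina/BGI di-nucleosomal fold:  2.63 (generator plants 2.6)
```

i.e. the fragment-size classifier recovers the platform insert-size bias the
generator planted. The comparison driver prints, per cell state, the union
size and the shared / platform-specific percentages, e.g.

```
mesc: 245 union peaks | shared 96.33% | illumina-only 1.63% | bgi-only 2.04%
  mean SPM shared 4527 vs platform-specific 333 (shared peaks score higher)
```

— platform-specific peaks are the weak, borderline-reproducible loci, so
their mean SPM sits far below the shared peaks', and every sample's nearest
neighbour in the count-matrix Euclidean distance is a replicate of the same
cell state, not the same platform. The integration driver ends with

```
top 5 nominated master TFs: Klf4, Pou5f1, Esrrb, Nr5a2, Sox2
```

recovering exactly the five planted pluripotency regulators ahead of the
enriched-but-not-differential decoy motifs.

The same stages are available as subcommands of the installed CLI
(`atacpeaks simulate|qc|consensus|compare|integrate`), each writing a JSON
run manifest with resolved parameters, input digests and per-stage record
counts.

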