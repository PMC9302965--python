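# Methods

`atacpeaks` implements the analysis layer of a sequencing-platform
comparison for OMNI-ATAC-seq libraries: library QC from fragment intervals,
construction of fixed-width reproducible consensus peak sets, shared vs
set-specific peak accounting between two consensus sets, and integration of
motif enrichment with expression to nominate master transcription factors.
Everything upstream of fragment intervals and narrowPeak calls (alignment,
deduplication, the peak caller itself) is out of scope; the package consumes
those artifacts and, for testing, generates synthetic stand-ins with known
truth.

## Coordinates and records

All coordinates are 0-based, half-open (BED native). A fixed-width peak of
width `2e + 1` centred on summit `s` spans `[s - e, s + e + 1)`; with the
default extension `e = 250` that is exactly 501 bp. The peak score used
throughout is the upstream caller's −log10 p-value (narrowPeak column 8),
not the display score in column 5. Chromosome Y records are dropped at parse
time by default so that all genomic comparisons run on the genome excluding
chrY. Fragments (sequenced pairs), never individual read mates, are the
counting unit.

## Fragment-size QC

Insert sizes are classified as sub-nucleosomal (< 147 bp), mono-nucleosomal
(180–247 bp), di-nucleosomal (315–473 bp), or `other`. The `other` class
covers the gap lengths (147–179, 248–314, > 473 bp) that the conventional
boundaries leave unassigned; making it explicit guarantees the reported
proportions partition and sum to 1.

Signal-to-background metrics use a ≥ 1 bp intersection rule:

* **FROT** — fraction of fragments intersecting any TSS ± 1 kb window. The
  window is exposed (`window=1000`); we interpret "within 1 kb of gene
  annotation" as TSS-anchored because the metric is used alongside the TSS
  enrichment profile.
* **FRiP** — peaks are first labelled proximal (intersecting a TSS ± 1 kb
  window) or distal; every fragment then lands in exactly one of
  `{tss_peaks, distal_peaks, not_in_peaks}`, with proximal peaks checked
  first so a fragment under both kinds of peak is counted as proximal. The
  precedence makes the three-way split deterministic.
* **TSS profile** — mean per-bin fragment coverage over strand-oriented
  TSS ± 1 kb windows (minus-strand windows reversed), default 10 bp bins.

Down-sampling to a fixed depth is a uniform random subset without
replacement, reproducible by seed.

## Consensus peak workflow

Per sample: summits are extended ± 250 bp to 501 bp windows (peaks whose
window would cross a chromosome end are dropped, not clipped — clipping
would break the fixed-width arithmetic that the 50 %-overlap rule relies
on); peaks touching a blacklist interval by ≥ 1 bp are removed; overlapping
peaks are resolved by **iterative removal**: repeatedly keep the most
significant remaining peak and discard every peak overlapping it by ≥ 1 bp.
Equal scores are broken by (chrom, start, sample id), smallest kept, so the
survivor set is deterministic; the implementation is a single score-ordered
sweep, which provably yields the same survivors and is verified in the tests
against a literal re-scanning oracle.

Scores are then converted to **score per million**:
`spm_i = score_i / (Σ_j score_j / 10^6)`, so each sample's SPM vector sums
to exactly 10^6 and scores become comparable across libraries that differ in
depth and overall quality.

**Replicate consensus**: all samples' prepared peaks are pooled and
iterative removal is rerun ranked by SPM. A survivor is retained when peaks
from ≥ 2 distinct samples, each with SPM ≥ 3, overlap it by at least 50 % of
the fixed width (251 of 501 bp; the survivor counts toward its own support
when it qualifies). The supporting sample's own peak must meet the SPM
threshold — a strong survivor cannot rescue weak support. Two points the
rule statement leaves open are resolved as follows: the pooled-stage
iterative removal uses the ≥ 1 bp rule (the 50 % threshold is attached only
to the reproducibility requirement), and one sample's peak may support
several distinct survivors (each survivor is evaluated independently).

**Cross-set consensus**: each input set's SPM vector is re-normalized to sum
to 10^6 (so a deeper or higher-quality set is not over-represented), the
sets are pooled, and iterative removal is rerun. Each surviving peak records
the input sets that contributed a ≥ 50 %-overlapping peak; that provenance
drives the shared / set-specific classification.

## Set comparison, annotation, shape, distances

`classify_peaks` splits a merged set into shared / a-only / b-only and
reports percentages of the union; counts partition exactly.

Genomic context uses the 40 % rule: an interval is assigned the
highest-precedence feature whose intersection covers ≥ 40 % of the
interval's own length, else `distal`. When several features qualify the
precedence is promoter > 5′UTR > 3′UTR > exon > intron; promoters-first
matches the promoter definition (TSS ± 1 kb) taking priority in genomic
context accounting. The denominator is always the query interval's length
(reads in the QC use, peaks when annotating consensus sets).

Peak shape is summarized from per-bp fragment coverage within the peak
window: `summit_height` is the coverage maximum, and `base_width` is the
maximal contiguous run containing the argmax with coverage ≥ half the
maximum. Using the contiguous run (not total bp above half-max) keeps the
metric robust to multi-modal noise.

Between-sample distances are plain Euclidean distances over per-sample
count vectors of the consensus peak matrix (optionally log1p-scaled;
default raw). `differential_rank` is deliberately a non-statistical
stand-in: log2 of the ratio of mean CPM with pseudocount 1, no dispersion
model, no p-values.

## Motif × expression integration

Expression is transformed to `log2(CPM + 1)` per replicate; the pseudocount
keeps zero counts at exactly 0 and makes the "> 2 log2CPM" robust-expression
floor meaningful. Condition-level expression is the arithmetic mean of
replicate log2CPM values (not the log of mean CPM). Motifs are collapsed to
one record per TF gene keeping the lowest-FDR motif — per-TF collapsing, a
stricter reading of "non-redundant" than motif-cluster collapsing, and
documented as such. The top-25 motifs by enrichment FDR are then filtered to
TFs expressed above the floor in the target condition and re-ranked by the
target-minus-background log2CPM difference; ties break by lower FDR, then
gene symbol. The top five re-ranked TFs are the nominated master
regulators. The motif→TF mapping is a required input column: motif naming
conventions differ across enrichment tools, so inferring the gene from the
motif id would be fragile.

## Synthetic study generator

The generator emulates the statistical structure of a two-cell-type
(mESC-like vs MEF-like), two-platform, three-replicate comparison at desk
scale. Defaults (all config-exposed):

* **Genome** 2 chromosomes, 12 + 8 Mb. **Planted regions**: 300
  non-overlapping 400 bp accessible regions, ~60 % accessible in both cell
  states and the rest state-specific. 30 % of regions are "weak" (strength
  uniform on 0.08–0.30, vs 1.0) so a realistic minority of loci sits near
  the detection limit — these produce the low-scoring, poorly reproducible
  peaks that drive the shared-vs-specific score stratification.
* **Depth** 30,000 fragments per sample with `frip_target = 0.35` drawn from
  planted regions (centre Gaussian around the region centre,
  sd = region_width/4), the rest uniform background. The depth is a
  desk-scale stand-in for the tens of millions of usable read pairs of a
  real library, chosen so the full 12-sample study simulates and analyses
  in well under two minutes.
* **Insert-size mixtures**: class-conditional lengths are sub uniform on
  [30, 146], mono discretized Gaussian(200, 20) truncated to [180, 247], di
  discretized Gaussian(400, 30) truncated to [315, 473], `other` uniform on
  the gaps. The within-class distributions are inventions (only the class
  boundaries are conventional). Default platform weights
  (w_sub, w_mono, w_di, w_other) are Illumina-like (0.40, 0.32, 0.13, 0.15)
  and BGI-like (0.52, 0.30, 0.05, 0.13), chosen to reproduce exactly the
  reported direction and fold of the platform bias: 1.3× more
  sub-nucleosomal fragments in BGI-like data and 2.6× more di-nucleosomal
  fragments in Illumina-like data.
* **Peak scorer**: a deliberately simple windowed Poisson-tail scorer stands
  in for the upstream caller so scores have an analytic oracle: 501 bp
  windows stepped by 100 bp, window fragment count `k` scored as
  −log10 P(X ≥ k), X ~ Poisson(background_rate × 501), candidates above
  score 2, summit at the window coverage argmax, plus Poisson-distributed
  noise peaks (2 per Mb, scores uniform on (2, 4]). `background_rate`
  defaults to 0.002/bp, above the raw background fragment density
  (~0.001/bp at default depth), because a window's overlap count sees each
  fragment along window + fragment length rather than at a single bp. The
  output intentionally contains overlapping candidates so iterative removal
  is exercised. Scores are capped at 1000 when the tail underflows.
* **Expression/motifs**: negative-binomial counts (dispersion 0.1), three
  replicates per condition. Planted master TFs (Pou5f1, Sox2, Klf4, Esrrb,
  Nr5a2) have mean 500 in the target state vs 1 in the background; "low"
  decoys (mean 2 in both) fall below the robust-expression floor; "flat"
  decoys (mean 1000 in both) pass the floor but have ≈ 0 expression
  difference. Planted motifs carry the smallest FDRs, then decoys, then
  filler motifs.

All randomness flows from the single root seed through
`numpy.random.SeedSequence` children keyed by purpose and sample index, so
any sample can be regenerated independently.

### What the generator does and does not emulate

It reproduces the features the pipeline's logic depends on: replicate
reproducibility, platform-specific insert-size mixtures, region-strength
heterogeneity, promoter-proximal vs distal context, noise peaks, and a
motif/expression structure with planted positives and decoys. It does not
model sequence content, Tn5 insertion-site or GC bias, PCR duplicates,
copy-number or mappability artifacts, or correlated biological variability
between replicates. Passing tests therefore demonstrate the correctness of
the analytical rules and their statistical behaviour under the assumed
generative model — not the end-to-end performance of the upstream
processing on real libraries.

## Numerical choices and degenerate inputs

SPM conservation is tested to 1e−9 relative tolerance. Iterative-removal
ties break by (chrom, start, sample id); expression re-ranking ties by
(FDR, gene symbol). Empty fragment sets, zero-score vectors, zero library
sizes, overlapping count-target peaks, summitless peaks, and unknown feature
labels all raise validation errors rather than propagating silently; an
empty TSS set in FROT returns 0 with a warning (a QC tool should degrade
gracefully there). Boundary-crossing fixed-width windows are dropped with a
logged count.

## Problem sizes used in tests

The default study (2 conditions × 2 platforms × 3 replicates, 30 k
fragments/sample, 300 regions, 20 Mb genome) was chosen so the complete
test suite, including ten-seed recovery sweeps and the 100-seed TF-recovery
property, runs in a few minutes on one CPU. Mixture-recovery properties use
50,000 fragments, where three binomial standard errors give a tight yet
noise-tolerant band.

## Known limitations

* `differential_rank` is plumbing, not statistics; real differential
  accessibility should use a count model with dispersion estimation.
* Per-TF motif collapsing may keep two motifs of paralogous TFs that a
  motif-cluster collapse would merge.
* The 40 % annotation rule assigns a single label; intervals genuinely
  spanning two features are resolved by precedence, not split.
* FRiP here is fragment-based; read-based FRiP from the same library would
  differ by up to a factor related to pair counting.
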