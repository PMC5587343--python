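# Methods

## Model and assumptions

The screen targets *passage-dependent promoter hypermethylation with
expression silencing* in cultured human pluripotent stem cells.  The
underlying model is deliberately simple:

* Methylation at a CpG probe is summarized by the β value, the fraction
  of methylated signal, in [0, 1].  Unmethylated CpG islands sit in a low
  mode (β ≈ 0.1), methylated non-island CpGs in a high mode (β ≈ 0.85).
* A drifting probe gains methylation approximately linearly in passage
  number p: β(p) = clip(β₀ + s·p, 0, 1), with s in β units per passage.
  The per-probe OLS slope of β against p therefore estimates s directly.
* Promoter island methylation silences the gene, so a drifting gene shows
  both Δβ > 0 between high- and low-passage groups and reduced
  expression, with negative β–expression correlation across samples.

Assumptions worth keeping in mind: β matrices are taken as already
normalized (range-scaling against control DNA is provided, but IDAT
processing, SWAN and batch correction are out of scope); samples are
treated as independent observations (no within-line nesting in the
regression); and "silencing" is only detectable for genes expressed above
the detection floor at low passage.

## Key parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `delta_beta_cutoff` | 0.2 | β | screen candidate threshold (strict `>`); large enough that chance excursions are rare at array noise levels |
| `fold_cutoff` | 1.5 | linear fold | expression silencing threshold (strict `>`), fold = median(low)/median(high) of linearized values |
| `expression_floor` | 5.0 | log2 | microarray detection floor; "unexpressed" ≡ value == floor.  A config parameter — there is no universal value; RNA-seq FPKM uses 0.5 on the linear scale |
| group modes | ≤25 / ≥50 (strict), ≤25 / >25 (permissive) | passage | strict mode gives clean separation; permissive mode is for compendia without very high passages |
| `window_genes` | 100 | genes | e-karyotype window; large enough that a single differentially expressed gene moves the window mean by only ~1/100 of its effect — small windows are confounded by ordinary single-gene regulation (verified: a 10-gene window mis-flags samples purely from planted drift-gene silencing) |
| `call_threshold` | 0.3 | log2 | half of a trisomy's expected dosage shift log2(3/2) ≈ 0.585; windows of 100 genes with per-gene noise σ ≈ 0.25 have σ/√100 = 0.025, so 0.3 is ≈12σ from 0 for diploid windows |
| `noise_threshold` | 0.17 | MAD, log2 | global-dispersion QC cutoff, calibrated as the 99th percentile of per-sample MAD over 1,200 simulated diploid samples at generator defaults (measured 0.155, rounded up) |
| FDR level | 0.05 | q | Benjamini–Hochberg across tested probes in the compendium validation |
| DE filter | mean fold > 2, replicate folds > 1.5, floor 0.5 FPKM | linear | two-replicate knockdown rule; replicate folds are taken against the control-arm mean (configurable to all-pairwise `each_vs_each`) |
| McrBC `call_threshold_ct` | 3.0 | qPCR cycles | ΔCt ≥ 3 ≈ 8-fold template loss in the digested reaction; a digested reaction that fails to amplify while the mock amplifies is itself a methylated call |

## The synthetic-data generator

`epidrift.simulate` emulates the statistical structure of matched
methylation/expression compendia of cultured hPSC lines:

* 6 lines × passages (5, 10, 15, 20, 25, 75, 85, 95, 105, 115) → 30
  low- and 30 high-passage samples, populating both group definitions.
* Baseline β per probe from bounded Beta distributions (islands
  Beta(1.5, 13.5), mean 0.10; open sea Beta(8.5, 1.5), mean 0.85), plus
  Gaussian measurement noise (σ = 0.03) added on the clipped linear
  predictor and re-clipped to [0, 1].
* 20 drift genes among 10,000 with slope 0.004 β/passage on island
  probes; at this passage spread the planted between-group Δβ is ≈0.32.
* Expression: per-gene baseline ~ N(8, 1.5) log2 with noise σ = 0.25;
  drift-gene expression is reduced by 10 log2-units per unit of the
  sample's *realized* (noisy) β gain, so methylation–expression
  correlation is negative by construction and the planted silencing is
  ≈9-fold between groups (a noise-free gain of 0.3 gives exactly 8-fold).
* Drift genes are planted only among autosomal genes expressed ≥ 2 log2
  units above the floor: a "silenced" gene that was never detectably
  expressed is not a coherent ground-truth event (its fold change is 1 by
  construction).
* 2 samples receive a +log2(1.5) expression shift on one random autosome
  (trisomy dosage); 5 % of genes are generated as unexpressed (below
  floor) to exercise the filters.
* A second "platform" shares exactly `round(overlap_fraction · n_genes)`
  genes (drift genes always shared; default 0.6), with fresh samples,
  probe ids and noise — the cross-dataset replication setting.

What it does **not** emulate: Infinium probe chemistry and type-I/II
bias, cross-reactive or SNP-affected probes, batch structure, line-level
correlation between repeated samples of one line, partial-population
(mosaic) aneuploidy, and region-level (multi-probe DMR) correlation
beyond shared gene membership.  Passing tests therefore demonstrate the
pipeline's statistical behaviour under its own model, not robustness to
array artefacts — on real data the upstream normalization is assumed to
have dealt with those.

## Numerical and design choices

* **Δβ aggregate.** Group means by default, group medians as an option
  (`beta_aggregate`); expression fold always uses medians of linearized
  (2^x) values.  Both aggregates agree exactly on symmetric noise-free
  data, which the test suite asserts.
* **Probe matching.** Methylation probes map to expression by shared gene
  symbol; a gene with several expression probes is represented by the
  probe with the highest mean expression (ties broken by probe id).
* **Correlation.** Pearson, across all matched samples (not within
  groups), NaNs excluded pairwise; probes with < 3 paired observations
  get NaN.
* **Missing β.** Propagated as NaN, excluded pairwise everywhere; probes
  missing in > 50 % of either group are dropped at the filter stage.
* **Unevaluable probes.** < 3 usable samples in either group ⇒ record
  kept but flagged, never a candidate.
* **Hypergeometric tail.** Summed in log space from log-gamma binomials
  (`logsumexp`), exact to ~1e-14 relative error against rational
  enumeration and stable for tails far below double underflow of the
  individual products.  The universe (genes evaluable in *both* datasets)
  is a required input, never a constant: overlap probabilities are
  meaningless without it, and published overlap p-values whose universe is
  unstated cannot be reproduced exactly.
* **Clustering.** Distance 1 − Pearson r (or Euclidean), complete
  linkage; the "two main branches" are the children of the dendrogram
  root (`fcluster` maxclust 2 — identical by construction).  Features
  with any missing value are dropped before distances; a sample with a
  constant profile is an error under Pearson distance (named in the
  message).  Dendrograms export to Newick.
* **Ranking ties.** `rank` is ordinal with probe-id tie-break (runs are
  reproducible byte-for-byte); `percentile` uses competition ranking so
  tied slopes share a percentile (all-equal input ⇒ all-equal
  percentiles).
* **DE filter symmetry.** With replicate folds taken against the
  control-arm mean (the default, matching the stated rule), swapping the
  arms is *not* exactly symmetric; the `each_vs_each` mode (all four
  pairwise folds > 1.5) is, and the suite asserts the swap symmetry in
  that mode.
* **Degenerate inputs.** Fisher tables with an empty margin report p = 1
  with a warning; chromosomes with fewer genes than the QC window are
  skipped with a warning; empty passage groups and all-identical passage
  vectors are errors.
* **Seeding.** One root seed; the generator and every pipeline stage
  derive their streams from `numpy.random.SeedSequence` spawn keys, so a
  config + seed pair reproduces byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run the full screen at the
reference conditions (10,000 genes, 20,000 methylation probes, 60
samples) over 10 generator seeds, plus 10 null (slope 0) seeds; unit
tests use smaller configurations (300–2,000 genes) chosen to keep the
whole suite under a minute while leaving every statistical check
well-powered.

## Known limitations

* The e-karyotype scan is a simplified reimplementation (median
  centering + fixed windows + two thresholds); it detects chromosome-scale
  shifts, not focal CNVs, and reports no breakpoints.
* Plain per-probe OLS ignores line identity; with few lines and strong
  line effects the slope SEs are optimistic (the screen uses only the
  point estimate and its genome-wide rank).
* The Wilcoxon validation treats probes as independent when applying BH.
* No DMR (region-level) calling and no covariate-adjusted differential
  methylation model — by design, the screen works at single-probe
  resolution with group contrasts.
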