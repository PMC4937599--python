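# Methods

This note documents the models behind each pipeline stage, the parameter
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that were genuinely open.

## The parainflammation model

Parainflammation (PI) is treated as a cell-autonomous transcriptional
program: a fixed set of inflammatory genes (the 40-gene up-signature) that
a subset of tumors switches on, each tumor activating its own subset of
the signature. The analysis therefore needs three ingredients: a signature
(derived from knockout-model differential expression), a per-sample
enrichment score robust to which particular subset is active (rank-based
ssGSEA), and a correction for the competing explanation that inflammatory
expression in bulk tumors merely reflects infiltrating leukocytes (the
CD45 adjustment).

## Differential expression engine

The two-group test is a negative-binomial Wald test in the standard bulk
RNA-seq style, reimplemented here rather than wrapped, because the
selection thresholds (fold ratio strictly > 2, BH-adjusted p < 0.01)
operate on its raw outputs:

- **Normalization**: median-of-ratios size factors over genes expressed
  in every sample.
- **Dispersion**: per-gene method-of-moments estimate from pooled
  within-group variance, moderated in log space toward a fitted
  α(μ) = a₀ + a₁/μ trend with prior weight equivalent to 4 degrees of
  freedom. With 2–3 replicates per group the trend dominates, which is
  the appropriate behavior at these sample sizes.
- **Fold change**: log2 of the ratio of pseudo-counted (+0.5) group means
  of normalized counts. No fold shrinkage is applied, since the selection
  threshold is on the raw fold ratio.
- **Test**: delta-method Wald statistic on the log2 fold change,
  Var(K·/sf) = μ/sf + αμ² per sample; BH correction over tested genes.
  Genes with all-zero counts are excluded.

On simulated data this engine agrees with pyDESeq2 (log2-fold correlation
> 0.99, call-set Jaccard > 0.8 on the test fixture), which serves as an
independent cross-check in the tests, never as the implementation.

Symbol handling: voting and intersections are case-insensitive
(uppercased), with the original casing preserved in outputs; ortholog
mapping drops and records unmapped symbols.

## Infiltration adjustment

Per tissue and gene, ordinary least squares of log2 expression on the
CD45 (*PTPRC*) log2 level over reference normals. Only the slope is
applied to tumors (intercepts are stored for diagnostics): subtracting
β·CD45 removes the infiltration-proportional component while leaving the
sample's own baseline. After subtraction every gene is shifted so its
minimum over the adjusted cohort is zero; the shift is computed within
the cohort being adjusted, not the training normals. Fitted negative
slopes are applied as fitted. The reference gene itself is never
slope-adjusted (its self-slope is identically 1, and removing it would
erase the infiltration readout); it does participate in the min-shift.
Tissues with fewer than 20 training samples are skipped with a warning;
if CD45 is absent from a cohort the adjustment refuses rather than
substituting a proxy. Whether values should additionally be floored
before the min-shift is undetermined by the procedure's description; the
min-shift makes outputs non-negative either way, so only within-gene
spacing could differ, and no extra flooring is applied.

## PI score

For one sample, genes are ordered by decreasing expression, ties broken
by gene symbol (deterministic across runs). With N genes, the gene at
position j carries rank value N − j + 1. The score is

  ES = Σ_i [ P_in(i) − P_out(i) ],

where P_in is the cumulative sum of rank^α over in-set genes, normalized
by its total, and P_out is the uniform ECDF of out-of-set genes. α = 0.25
by default (the de-facto ssGSEA convention; α = 1 reproduces fully
rank-weighted scoring and α = 0 the unweighted statistic). The statistic
is purely rank-based: any per-sample monotone transform of expression
leaves it unchanged.

Two properties verified by simulation and worth knowing:

- With α = 0 the score has mean exactly zero under random placement of
  the signature. For α > 0 the weighted in-set ECDF is biased toward the
  top of the list, so the permutation mean is slightly positive (about
  10% of the maximal score at α = 0.25). Tests assert exact centering at
  α = 0 and bounded relative bias at the default.
- The score is compositional: promoting one gene set demotes the ranks of
  every other. In small gene universes (hundreds of genes) this induces
  spurious negative correlations between set scores; at realistic
  universe sizes (thousands to tens of thousands of genes) the effect is
  negligible. Synthetic analyses in this package use ≥1000-gene universes
  where cross-set correlations matter.

**Cohort scoring** drops signature genes absent from the matrix (warning;
refusal below 50% coverage, configurable) and by default divides raw
scores by their cohort range, which is why quoted thresholds are sub-unit
values. Scores live on a platform/universe-specific scale: a
:class:`Threshold` records the universe it was calibrated on and
classification refuses a mismatched universe.

**Calibration**: the threshold is the (1 − f) linear-interpolation
quantile of pooled adjacent-normal scores, f = 0.05 by default.
For some n the interpolated quantile leaves marginally more than f·n
values strictly above it; in that case the threshold moves up to the
smallest order statistic restoring the guarantee, so the fraction of
calibration normals strictly above the threshold is always ≤ f.
Classification is strict: a sample exactly at the threshold is PI−.
Per-tissue calibration is available but pooling is the default.

## Overexpression statistic

Per gene over a cell-line panel: Gaussian KDE (Silverman bandwidth)
evaluated on a fixed 512-point grid spanning [min, max]; the peak is the
grid argmax (smallest location on ties — deterministic), and a line
overexpresses the gene when its log2 value strictly exceeds peak + δ,
δ = 1.0 (twofold) by default. KDE was chosen over histogram binning to
make the mode estimator continuous and testable; the grid size is fixed
for determinism. Pool comparisons report the proportion of genes with
rate ≥ 10% (chi-square, no continuity correction) and the median
overexpressing-line count (two-sided rank-sum), with seeded
without-replacement subsampling when pools are matched to the target
size.

## Association statistics

All tests are two-sided. Rank-sum tests use the Mann–Whitney U
(scipy). Survival models go through lifelines: Cox proportional hazards
with Efron handling of ties (returns the log hazard ratio per unit score
and its Wald p; optional controls, e.g. age, smoking, p53, and optional
stratification by cancer type), and Kaplan–Meier with a two-sided
log-rank test. The median-survival ratio is reported as PI− median over
PI+ median and only when both groups reach 50% mortality. The cytolytic
metric is the geometric mean of GZMA and PRF1 on the linear scale
(log2 input exponentiated), with an optional pseudo-count for zeros.
Correlation of the PI score with other gene-set programs uses the same
ssGSEA engine on each set and Spearman's ρ, pooled and per cancer type.

## Synthetic cohorts

The generators produce data with the statistical structure the analysis
assumes, with ground truth recorded for recovery tests.

- **Reference normals**: x = baseline_g + β_{g,t}·CD45_s + N(0, σ), with
  CD45 ~ N(4, 1) log2, slopes a zero-inflated Gaussian (50% zero,
  otherwise N(0.6, 0.4²), sign unrestricted), baselines N(5, 1.5²),
  σ = 0.5 by default. The CD45 row equals the infiltration level exactly
  — the marker itself is the latent variable, as in the real analysis.
  Slopes and baselines are drawn from a dedicated seed substream shared
  with the tumor-cohort generator, so a model trained on reference
  normals transfers to the cohort generated from the same seed.
- **Tumor cohort**: tumors and adjacent normals share the infiltration
  model. A fraction (default 0.259, the observed pan-cancer PI+ rate) of
  tumors activates the program: each PI+ tumor shifts a
  Binomial(40, 17/40) subset of signature genes by N(2.0, 0.5²) log2
  (floored at 0.25), reproducing both the reported median of ~17 active
  genes and the sample-to-sample heterogeneity of active subsets. The
  per-sample latent intensity (summed activation per signature gene)
  drives p53 status (logistic: intercept −0.85, coefficient 1.2, giving
  ~30% mutation in PI− and ~59% in PI+ tumors), the down-set coupling,
  and survival. The down-set (75 genes) and any "co-activated" genes
  shift proportionally to the latent intensity, which is what makes up-
  and down-derived scores positively correlated across samples, as
  observed empirically.
- **Survival**: exponential event times with hazard
  λ_s = λ₀·exp(b·intensity_s), λ₀ = 1/1500 days, b = 0.8; censoring by
  an independent Uniform(0, m) time with m solved so the expected
  censored fraction at the baseline hazard equals the configured rate
  (default 0.3). Independent censoring keeps the Cox coefficient
  recoverable.
- **Cell-line panel**: signature genes are two-component Gaussian
  mixtures (high component +3 log2, membership 0.2 per gene×line,
  component sd 0.3); background genes single Gaussians; CD45 is constant
  low (cell lines carry no infiltrate).
- **Counts**: NB counts with mean library_size·q_g·2^lfc and dispersion
  0.05; a wild-type and two knockout conditions with two replicates each
  by default, matching the knockout-model design. A shared DE core
  (60% of DE genes) with a known overlap with a designated inflammatory
  list makes the expected derived signature known by construction.

Not emulated (deliberately): gene-level marginal distributions of real
compendia, batch effects, isoform structure, within-cancer-type variance
of activation strength (exposed as config parameters but not calibrated
to any dataset). Passing recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not performance
on any particular real cohort.

## Problem sizes and determinism

All generators are bit-reproducible for a fixed seed; every stochastic
operation (pool subsampling included) takes an explicit seed. The
end-to-end test runs at 2000 genes × 2500 samples; slope-recovery
properties are checked at 200 samples/tissue and Cox recovery at 2000
tumors, sizes at which the stated tolerances (|β̂ − β| < 0.1, hazard
coefficient ±0.15, PI+ rate ±5 points) hold with comfortable margin.

## Known limitations

- The exact scale of published PI thresholds (0.2951 for the tumor
  compendium, 0.1859 for cell lines) depends on the original pipeline's
  unstated ssGSEA normalization and gene universe, and cannot be
  reproduced without that pipeline; thresholds here are calibrated on
  normals instead, which is the operation that defines them.
- The DE engine's dispersion moderation is simpler than full empirical
  Bayes; on 2-replicate designs small count differences near the
  thresholds can flip borderline genes relative to other implementations.
- The peak detector's bandwidth choice (Silverman) is a documented
  decision; other bandwidths move peak estimates slightly on real
  panels.
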