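# parainflam

Tools for detecting **parainflammation (PI)** — a low-grade, cancer-cell-
autonomous inflammatory transcriptional state — in bulk tumor expression
data, and for quantifying its clinical associations.

The package is aimed at computational cancer biologists working with
gene-by-sample expression matrices (TCGA-style tumor cohorts, GTEx-style
reference normals, CCLE-style cell-line panels) and knockout-model RNA-seq
counts. It implements the full analysis as a tested pipeline:

1. **Signature derivation** (`signature_derivation`). An inflammatory gene
   universe is assembled by majority vote over curated databases; genes
   upregulated (fold ratio > 2, BH-adjusted p < 0.01, negative-binomial
   Wald test) in each of two knockout models versus wild type are
   intersected with that universe to give the up-signature, with a
   symmetric down-signature and a correlation-based expansion
   (genes with Spearman ρ > 0.5 against the PI score).
2. **Infiltration adjustment** (`infiltration_adjustment`). Bulk tumors mix
   tumor cells with infiltrating leukocytes. For each gene *g* and tissue
   *t*, an OLS slope β<sub>g,t</sub> of log2 expression against the
   pan-hematopoietic marker CD45 (*PTPRC*) is learned on reference
   normals; tumor expression is corrected as
   x′<sub>g,s</sub> = x<sub>g,s</sub> − β<sub>g,t(s)</sub>·CD45<sub>s</sub>,
   then each gene is shifted so its cohort minimum is 0.
3. **PI scoring** (`pi_scoring`). The PI score of a sample is a
   single-sample GSEA statistic: with genes ranked by decreasing
   expression, the score integrates the difference between the
   rank-weighted (rank<sup>α</sup>, α = 0.25) in-set ECDF and the uniform
   out-of-set ECDF. The PI+ threshold is the (1 − f) quantile of
   adjacent-normal scores (f = 5%); samples strictly above it are PI+.
4. **Overexpression statistics** (`overexpression_stats`). On cell-line
   panels, each gene's expression mode is located by Gaussian KDE and a
   line "overexpresses" the gene when it exceeds the mode by > 1 log2
   (twofold); per-gene rates are compared between the signature and
   background gene pools (chi-square, rank-sum).
5. **Associations** (`association`). Spearman correlations with other
   gene-set scores, the two-gene cytolytic-activity metric
   (√(GZMA·PRF1), linear scale), p53-mutation enrichment, Cox
   proportional-hazards and Kaplan–Meier/log-rank survival models, and a
   rank-sum test for signature downregulation under NSAID treatment.
6. **Synthetic cohorts** (`synthetic_data`). Generators for all four input
   types with known ground truth (slopes, PI status, activated genes,
   embedded fold changes, hazard coefficient), so every stage has a
   parameter-recovery test.

## Worked example

```python
import parainflam as pf

cfg = pf.SimConfig(seed=11, n_genes=2000, n_tumors_per_tissue=1000,
                   n_normals_per_tissue=250, pi_positive_fraction=0.25,
                   n_inflammatory_genes=300)
normals, _ = pf.simulate_reference_normals(cfg)     # GTEx-like training set
cohort, ann, truth = pf.simulate_tumor_cohort(cfg)  # TCGA-like cohort

model = pf.fit_infiltration_slopes(normals)         # CD45 slopes per tissue
adjusted = pf.adjust_expression(cohort, model).matrix

scores = pf.score_cohort(adjusted, truth.signature.up)
is_normal = ann.sample_class == "normal"
thr = pf.calibrate_threshold(scores.raw[is_normal])  # 5% of normals above
called = pf.classify_samples(scores, thr.value)

frac = (called.calls[~is_normal] == "PI+").mean()
print(f"threshold {thr.value:.4f}; {frac:.1%} of tumors called PI+")
```

Output:

```
threshold 0.2210; 28.6% of tumors called PI+
```

The threshold is the score only 5% of adjacent normals exceed; the tumor
PI+ rate recovers the embedded 25% activation fraction (the few extra
points are borderline samples whose partial activation clears the normal
calibration bound). Downstream, `cox_survival` on the same cohort's
survival annotations returns the log hazard ratio per unit PI intensity
(0.775 against a generating coefficient of 0.8), and `p53_association`
recovers the positive PI–p53 link built into the simulation.

A thin CLI mirrors the library:

```
parainflam simulate cohort --config cfg.yaml --out sim/ --seed 11
parainflam fit-slopes --normals normals.tsv --annotations ann.tsv --out model.json
parainflam adjust --cohort expr.tsv --annotations ann.tsv --model model.json --out adjusted.tsv
parainflam score --expr adjusted.tsv --signature sig.json --out scores.tsv
parainflam calibrate --scores normal_scores.tsv --fraction 0.05
parainflam classify --scores scores.tsv --threshold 0.2951 --out called.tsv
```

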