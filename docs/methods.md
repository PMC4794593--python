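# Methods

## The analysis model

The package treats a cancer cohort as four linked observational layers:
a gene × sample expression matrix (RSEM or RPKM scale) over tumor and
adjacent-normal samples; somatic mutation calls (MAF rows) for tumors; a
probe × sample HumanMethylation450 β-value table (β = methylated probe
intensity / total intensity ∈ [0, 1]) with probe → gene/TSS annotation;
and per-patient follow-up (time in days, death event, covariates). The
five analyses ask, in order: does glycosylase expression track mutation
burden across cancer types; does it track burden within a cancer type when
tumors are dichotomized at a fold-multiple of the normal median; is low
expression explained by promoter hypermethylation; does low expression
predict survival; and is the *NEIL3* anomaly (high expression, high
burden) explained by co-expression with the mutagen *APOBEC3B*.

## Statistical conventions

All tests are two-sided with α = 0.05 and no multiple-testing correction;
result tables carry the number of tests so users can correct downstream.
Fixed conventions, chosen once for reproducibility:

* **Ranks** — mid-ranks for ties everywhere.
* **Mann-Whitney U** — exact enumeration of all C(N, n_a) labelings when
  n_a + n_b ≤ 12 and the data are tie-free; otherwise normal approximation
  with tie-corrected variance and 0.5 continuity correction. The two-sided
  exact P sums both tails at the observed distance from the null mean
  (the U distribution is symmetric).
* **Spearman** — ρ is the Pearson correlation of mid-ranks; exact
  permutation P for n ≤ 8, else the t approximation with n − 2 df.
* **Wilcoxon matched pairs** — zeros dropped, W = smaller signed-rank sum,
  exact 2^n sign-pattern enumeration for ≤ 15 nonzero pairs, else normal
  approximation with tie correction.
* **Kaplan-Meier / log-rank** — product-limit estimate; k-sample log-rank
  with hypergeometric variance, χ² on k − 1 df (risk sets of size 1 are
  skipped in the variance, as standard).
* **Cox proportional hazards** — Newton maximization of the Breslow
  partial likelihood (Efron available behind a flag), covariates
  standardized internally for conditioning and back-transformed, step
  halving on non-improving steps, convergence tolerance 1e-9 on the step;
  Wald 95% CIs. Non-convergence is flagged on the result, never silent.
* **P values** are floored at machine epsilon and printed as `<1e-16`,
  never 0.

Small-sample discrepancies against other software's tie/continuity
conventions are expected at the third decimal; the test suite pins our
conventions against scipy and lifelines where they coincide.

## Dichotomization and mutation loads

The reference for dichotomization is the median expression of the gene in
normal samples of the same cohort. Boundary convention (not dictated by
the underlying analyses, fixed here): "reduced" rules use strict
`value < cutoff·reference`, "elevated" rules use inclusive
`value ≥ cutoff·reference`, so symmetric edge cases partition
deterministically. Dichotomization is scale-invariant by construction.

Mutation loads count MAF rows per sample by variant type. SNP-type counts
single-nucleotide exchanges only; DNP/TNP/ONP rows count toward the total
(and `other_count`) but not the SNP-type load. Loads per Mb divide by a
configurable capture size, default 38 Mb (a typical whole-exome capture);
every cross-sample rank statistic is invariant to this constant and
reports echo the value used. Unrecognized variant-type strings map to
OTHER and are tallied in a parse report that accounts for every input row.

## The silencing classifier

Criteria and default thresholds: mean normal β < 0.4; 90th percentile of
tumor β (linear interpolation between order statistics) minus mean normal
β > 0.1; mean normal expression / mean expression of the top-β tumor
decile > 1.5; Spearman ρ(β, expression) < −0.25. The call is the AND of
the four flags, so hardening any threshold is monotone (never converts a
negative call to positive). The top-β slice takes k = ⌈0.10 · n_tumor⌉
samples, β ties broken by sample ID — k ≥ 1 and deterministic. Criterion 4
uses tumor and normal samples jointly by default (both tissues inform the
inverse coupling; a tumors-only mode exists). Expression enters criteria
3–4 raw, not housekeeping-normalized: the quantity of interest is the
gene's own level against its own promoter methylation. Missing β values
stay NaN and are excluded pairwise — silent zeros would bias the normal
mean of criterion 1 downward.

Cohorts without their own normal tissue run in a fallback mode: an
externally supplied normal expression mean (e.g. from another cohort of
the same organ) substitutes in criterion 3, and optionally a normal β mean
in criteria 1–2; the decision is flagged `fallback_used`. Probe choice:
a configured probe ID wins; otherwise the annotated probe within the TSS
window whose β is most negatively rank-correlated with expression, ties
lexicographic.

## The synthetic generator

`SimConfig`/`generate_cohort` emulate a mid-sized TCGA cohort. Defaults:
200 tumors, 30 normals, ~100 somatic exome mutations per tumor with 90%
single-nucleotide (the remainder split evenly between insertions and
deletions), promoter β centred at 0.2 in normal tissue with Beta
concentration 20, log-normal expression noise of 0.5 on the log scale
(strictly positive and heavy-tailed like RSEM values), housekeeping
baseline 10× the target genes. Planted effects: a silenced tumor subset
whose target-gene expression is multiplied by a factor in (0, 1) and whose
promoter β mean is shifted up (mean clipped into (0, 1) before the Beta
draw); Poisson mutation counts whose log-rate increases by `load_coupling`
in that subset; exponential survival with a proportional planted hazard
ratio for the subset and independent exponential censoring (closed-form
truth for recovery tests); an optional shared standard-normal latent
factor with per-gene loadings planting co-expression.
`generate_multi_cancer` grades the target gene's expression scale
log-linearly across cohorts and couples the mutation rate to `trend` times
that gradient plus independent per-cohort jitter, so `trend = 0` plants
exact independence and sign(`trend`) is the planted monotone relation.

What the generator does **not** emulate: mutational signatures and their
sequence context, copy-number and structural variation, batch effects and
purity, probe-specific 450K measurement error, correlated censoring, or
realistic covariate-outcome confounding. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
generative model, not robustness to the full messiness of real TCGA data.

## Problem sizes and numerical choices

The recovery suites use deliberately scaled simulations chosen to give the
binomial checks more precision than the bands they assert: classifier
sensitivity/specificity over 200 planted + 200 null cohorts of 200 tumors
(β shift 0.3, expression factor 0.3, 30% silenced); cross-cancer sign
recovery over 100 panels of 13 cohorts (60 tumors each) and the null rate
over 300 panels — at 100 panels the binomial noise of a ~5% rate (±2.2
points) would exceed the 3–8% acceptance band itself; Mann-Whitney size
over 2000 null draws of 20 + 20; Cox Wald-CI coverage of a planted hazard
ratio of 2 over 500 cohorts of 500 tumors. Deterministic seeds throughout;
identical config + seed reproduces bundles and reports byte-identically
(JSON is key-sorted, tables written with fixed column order).

## Known limitations

* The Cox implementation covers right censoring with time-fixed
  covariates only (no stratification, no time-varying effects).
* The silencing classifier evaluates one probe at a time; multi-probe
  aggregation (e.g. region-level averaging) is out of scope.
* Duplicate tumor aliquots per patient are not collapsed; the tables keep
  one column per sample ID and leave aliquot policy to the caller.
* Published-table worked examples check the decision logic against
  printed summary values; the original cohort-level TCGA numbers are not
  reproducible without the archived snapshot those analyses used.
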