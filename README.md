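# glycoburden

Analysis pipeline linking the expression of the DNA-glycosylase genes
*NEIL1*, *NEIL2* and *NEIL3* — base-excision-repair enzymes that excise
mutagenic base lesions — to the somatic mutation burden of tumor cohorts.
It is written for computational cancer biologists who want to re-run or
probe this style of pan-cancer TCGA analysis on their own cohorts, or to
study its statistical behaviour on simulated data with known ground truth.

The pipeline chains five analyses over linked expression / mutation /
methylation / clinical layers of one or many cohorts:

1. **Cross-cancer correlation** — per cohort, the median over tumors of
   gene expression normalized sample-wise to the housekeeping gene *YWHAZ*,
   against the median somatic mutation load per Mb (total, and SNP-type
   only: single-nucleotide exchanges, excluding insertions/deletions);
   Spearman's ρ across cohorts.
2. **Dichotomized load association** — tumors split at a fold-multiple of
   the normal-tissue median expression (0.5× for reduced *NEIL1*/*NEIL2*,
   2.5× for elevated *NEIL3*, per-cohort overrides supported); Mann-Whitney
   *U* comparison of loads between the abnormal and other groups.
3. **Epigenetic-silencing screen** — a four-criterion promoter-
   hypermethylation classifier at a CpG probe near the TSS, calling a gene
   silenced in a cohort iff (1) mean normal-tissue β < 0.4, (2) 90th
   percentile of tumor β minus mean normal β > 0.1, (3) mean normal
   expression over the mean expression of the 10% of tumors with the
   highest β exceeds 1.5, and (4) Spearman ρ(β, expression) < −0.25; plus
   the hypermethylated-tumor percentage (β > normal mean + 0.15).
4. **Survival stratification** — Kaplan-Meier curves, log-rank test and
   uni-/multivariate Cox proportional hazards (Breslow ties, Wald CIs) for
   the dichotomized expression group.
5. **Co-expression screen** — association of *NEIL3* with the mutagenic
   cytidine deaminase *APOBEC3B* (group comparison + rank correlation).

All rank and survival statistics are implemented in-house with fixed,
documented conventions (mid-ranks, exact enumeration at small n, tie
corrections, continuity correction); scipy and lifelines serve as
independent oracles in the test suite. A synthetic cohort generator with
planted effects (silenced tumor fraction, expression knockdown, β shift,
load coupling, hazard ratio, shared co-expression factor) provides ground
truth for every stage.

## Worked example

Running the simulated default study (13 cohorts of 200 tumors + 30
normals; *NEIL1* silencing planted in four cohorts, a hazard ratio of 2 in
one, opposite cross-cancer trends for *NEIL1* and *NEIL3*):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_cross_cancer_correlation.py
```

prints, among other rows:

```
 gene load_type     rho      p_value  n_cohorts
NEIL1     total -0.9835 1.611215e-09         13
NEIL3     total  0.9890 1.750728e-10         13
```

i.e. across the 13 simulated cohorts, median normalized *NEIL1* expression
falls as the median mutation load per Mb rises (ρ = −0.98), while *NEIL3*
rises with it (ρ = 0.99) — the planted trends, recovered with two-sided
P ≪ 0.05. `analysis/04_silencing_screen.py` then calls exactly the four
planted cohorts silenced for *NEIL1* (and never *NEIL2*/*NEIL3*):

```
cancer_label  gene   probe_id  delta_beta  fold_change    rho  hypermethylated_tumor_pct
       SIM01 NEIL1 cg00000001       0.471        5.789 -0.705                       44.0
       ...
4 (cohort, gene) pairs called silenced (4 of them NEIL1, as planted).
```

and `analysis/05_survival.py` finds significant log-rank separation only
in the planted hazard-ratio cohort (SIM02: HR 2.14, 95% CI 1.53–2.99).
The remaining drivers (`03`, `06`, `07`) cover the dichotomized load
associations, the *NEIL3*/*APOBEC3B* co-expression screen and the
published-table worked examples; each writes its table under `results/`.

A CLI mirrors the library for file-based use: `glycoburden simulate`,
`loads`, `silencing`, `associate`, `survival`, `run` (see `--help`).

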