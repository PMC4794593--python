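"""Orchestration of the five cohort analyses plus IHC scoring.

Stages (each consumes one or many CohortBundles and emits rows of a result
table):

* ``stage_cross_cancer`` — cohort-level Spearman correlation of median
  housekeeping-normalized target-gene expression with median mutation load
  per Mb;
* ``stage_dichotomized_association`` — Mann-Whitney comparison of
  per-sample loads between the abnormal-expression group and the rest;
* silencing screen — `glycoburden.silencing` applied per cohort (driven by
  ``run_pipeline``);
* ``stage_survival`` — Kaplan-Meier / log-rank and uni- + multivariate Cox
  on the dichotomized expression group;
* ``stage_coexpression`` — group comparison and rank correlation of a
  second gene against the dichotomized target gene.

Stage failures never abort a multi-cohort run: the affected row is flagged
``untestable``/``error`` and the remaining cohorts complete (cohort sizes
differ wildly in practice and small cohorts legitimately fail
preconditions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, GlycoburdenError
from .expression_mutload import (
    DEFAULT_CAPTURE_MB,
    DichotomyRule,
    dichotomize,
    median_normal_expression,
    mutation_loads,
    normalize_to_housekeeping,
)
from .io_formats import survival_frame, write_report
from .silencing import SilencingThresholds, evaluate_silencing, select_probe
from .stats_core import (
    CorrelationResult,
    SurvivalFit,
    cox_ph,
    km_logrank,
    mann_whitney_u,
    spearman,
    wilcoxon_signed_rank,
)
from .synthetic_data import CohortBundle, SimConfig, generate_cohort


# ---------------------------------------------------------------------------
# IHC scoring


@dataclass
class IHCScore:
    """Intensity-weighted immunostaining score on a 0/1/2 scale, range 0-200."""

    case_id: str
    tissue: str
    pct_intensity_0: float
    pct_intensity_1: float
    pct_intensity_2: float
    score: float


def ihc_score(pct_intensity_0: float, pct_intensity_1: float, pct_intensity_2: float,
              case_id: str = "", tissue: str = "tumor") -> IHCScore:
    """Score = sum of (percent of cells x staining intensity), 0-200."""
    pcts = (pct_intensity_0, pct_intensity_1, pct_intensity_2)
    if any(p < 0 for p in pcts):
        raise DataError("intensity percentages must be >= 0")
    if abs(sum(pcts) - 100.0) > 0.01:
        raise DataError(f"intensity percentages must sum to 100, got {sum(pcts)}")
    score = 0.0 * pct_intensity_0 + 1.0 * pct_intensity_1 + 2.0 * pct_intensity_2
    return IHCScore(
        case_id=case_id,
        tissue=tissue,
        pct_intensity_0=pct_intensity_0,
        pct_intensity_1=pct_intensity_1,
        pct_intensity_2=pct_intensity_2,
        score=score,
    )


def ihc_paired_compare(tumor_scores, normal_scores, alpha: float = 0.05):
    """Wilcoxon matched-pairs test on per-case tumor - normal score differences."""
    t = np.asarray([s.score if isinstance(s, IHCScore) else s for s in tumor_scores], float)
    n = np.asarray([s.score if isinstance(s, IHCScore) else s for s in normal_scores], float)
    if t.shape != n.shape:
        raise DataError("tumor and normal score lists must pair up")
    return wilcoxon_signed_rank(t - n, alpha=alpha)


# ---------------------------------------------------------------------------
# Stage helpers


def _cohort_loads(cohort: CohortBundle, capture_mb: float) -> pd.DataFrame:
    return mutation_loads(cohort.mutations, cohort.expression.tumor_samples, capture_mb)


def count_significant(table: pd.DataFrame, column: str, alpha: float = 0.05) -> int:
    """Rows of a stage table with P < alpha in ``column`` (NaN = untestable,
    excluded)."""
    if table.empty:
        return 0
    if column not in table.columns:
        raise DataError(f"unknown P-value column {column!r}")
    if not 0 < alpha <= 1:
        raise DataError(f"alpha must be in (0, 1], got {alpha}")
    p = pd.to_numeric(table[column], errors="coerce")
    if alpha == 1:  # the degenerate bound counts every testable row
        return int(p.notna().sum())
    return int((p < alpha).sum())


def stage_cross_cancer(
    cohorts: list[CohortBundle],
    gene: str,
    hk_gene: str,
    load_type: str = "total",
    capture_mb: float = DEFAULT_CAPTURE_MB,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Cohort-level correlation of normalized expression with mutation load.

    For each cohort: median over tumors of gene/housekeeping expression and
    median load per Mb (over tumors carrying both layers); then Spearman
    across the cohort-level pairs.
    """
    if len(cohorts) < 3:
        raise DataError("need >= 3 cohorts for a cross-cancer correlation")
    load_col = {"total": "total_per_mb", "snp": "snp_per_mb"}[load_type]
    rows = []
    for c in sorted(cohorts, key=lambda c: c.cancer_label):
        tumors = c.expression.tumor_samples
        norm = normalize_to_housekeeping(c.expression, gene, hk_gene)[tumors]
        loads = _cohort_loads(c, capture_mb)[load_col]
        rows.append(
            {
                "cancer_label": c.cancer_label,
                "median_normalized_expression": float(norm.median()),
                "median_load_per_mb": float(loads.median()),
                "n_tumors": len(tumors),
            }
        )
    medians = pd.DataFrame(rows)
    corr = spearman(
        medians["median_normalized_expression"], medians["median_load_per_mb"], method="approx"
    )
    return corr, medians


def stage_dichotomized_association(
    cohort: CohortBundle,
    gene: str,
    rule: DichotomyRule,
    load_type: str = "total",
    capture_mb: float = DEFAULT_CAPTURE_MB,
    alpha: float = 0.05,
) -> dict:
    """Mann-Whitney load comparison between abnormal and other tumors."""
    load_col = {"total": "total_per_mb", "snp": "snp_per_mb"}[load_type]
    reference = median_normal_expression(cohort.expression, gene)
    tumors = cohort.expression.tumor_samples
    values = cohort.expression.values.loc[gene, tumors]
    groups = dichotomize(values, rule, reference, cohort=cohort.cancer_label)
    loads = _cohort_loads(cohort, capture_mb)[load_col]
    abnormal = loads[groups[groups == "abnormal"].index]
    other = loads[groups[groups == "other"].index]
    row = {
        "cancer_label": cohort.cancer_label,
        "gene": gene,
        "stage": "dichotomized_association",
        "load_type": load_type,
        "n_abnormal": len(abnormal),
        "n_other": len(other),
        "alpha": alpha,
        "untestable": False,
    }
    if len(abnormal) == 0 or len(other) == 0:
        row.update(untestable=True, mwu_u=np.nan, mwu_p=np.nan, direction="none",
                   median_abnormal=np.nan, median_other=np.nan, significant=False)
        return row
    comp = mann_whitney_u(other, abnormal, alpha=alpha)
    row.update(
        median_other=comp.median_low,
        median_abnormal=comp.median_high,
        mwu_u=comp.u_statistic,
        mwu_p=comp.p_value,
        direction=comp.direction,
        significant=comp.p_value < alpha,
    )
    return row


def stage_coexpression(
    cohort: CohortBundle,
    gene_a: str,
    gene_b: str,
    rule_a: DichotomyRule,
    alpha: float = 0.05,
) -> dict:
    """Association of gene_b expression with gene_a's dichotomized status.

    Reports both the Mann-Whitney comparison of gene_b between gene_a
    groups and the tumor-level Spearman correlation of the two genes.
    """
    for g in (gene_a, gene_b):
        if g not in cohort.expression.values.index:
            raise DataError(f"gene {g!r} not in expression matrix")
    tumors = cohort.expression.tumor_samples
    reference = median_normal_expression(cohort.expression, gene_a)
    groups = dichotomize(
        cohort.expression.values.loc[gene_a, tumors], rule_a, reference, cohort=cohort.cancer_label
    )
    b_values = cohort.expression.values.loc[gene_b, tumors]
    abnormal = b_values[groups[groups == "abnormal"].index]
    other = b_values[groups[groups == "other"].index]
    row = {
        "cancer_label": cohort.cancer_label,
        "gene": f"{gene_a}~{gene_b}",
        "stage": "coexpression",
        "n_abnormal": len(abnormal),
        "n_other": len(other),
        "alpha": alpha,
        "untestable": False,
    }
    if len(abnormal) == 0 or len(other) == 0:
        row.update(untestable=True, mwu_u=np.nan, mwu_p=np.nan, direction="none",
                   median_abnormal=np.nan, median_other=np.nan)
    else:
        comp = mann_whitney_u(other, abnormal, alpha=alpha)
        row.update(
            median_other=comp.median_low,
            median_abnormal=comp.median_high,
            mwu_u=comp.u_statistic,
            mwu_p=comp.p_value,
            direction=comp.direction,
        )
    corr = spearman(
        cohort.expression.values.loc[gene_a, tumors],
        b_values,
        method="approx",
    )
    row.update(rho=corr.rho, rho_p=corr.p_value, n_pairs=corr.n)
    return row


def stage_survival(
    cohort: CohortBundle,
    gene: str,
    rule: DichotomyRule,
    covariates: tuple[str, ...] = ("age", "stage"),
    alpha: float = 0.05,
) -> SurvivalFit:
    """KM / log-rank / Cox for the dichotomized expression group.

    The univariate Cox uses the abnormal-group indicator alone; the
    multivariate fit adds whichever configured covariates the clinical
    records carry.  Unjoinable clinical samples are listed in ``extras``.
    """
    reference = median_normal_expression(cohort.expression, gene)
    tumors = cohort.expression.tumor_samples
    groups = dichotomize(
        cohort.expression.values.loc[gene, tumors], rule, reference, cohort=cohort.cancer_label
    )
    clin = survival_frame(cohort.clinical)
    joinable = clin["sample_barcode"].isin(groups.index)
    unjoined = list(clin.loc[~joinable, "sample_barcode"])
    clin = clin[joinable].copy()
    if clin.empty:
        raise DataError("no clinical records joinable to expression samples")
    clin["abnormal"] = (groups[clin["sample_barcode"]].to_numpy() == "abnormal").astype(int)
    by_group = {
        label: sub for label, sub in clin.groupby(clin["abnormal"].map({1: "abnormal", 0: "other"}))
    }
    if len(by_group) < 2:
        raise DataError("all tumors fall in one expression group: survival comparison degenerate")
    fit = km_logrank(by_group)
    uni = cox_ph(clin, ["abnormal"])
    multi_covs = ["abnormal"] + [c for c in covariates if c in clin.columns]
    multi = cox_ph(clin, multi_covs) if len(multi_covs) > 1 else uni
    fit.cox = uni.cox
    fit.converged = uni.converged and multi.converged
    fit.extras = {
        "cancer_label": cohort.cancer_label,
        "gene": gene,
        "alpha": alpha,
        "n_abnormal": int(clin["abnormal"].sum()),
        "n_other": int((1 - clin["abnormal"]).sum()),
        "multivariate": multi.cox,
        "unjoined_samples": unjoined,
    }
    return fit


# ---------------------------------------------------------------------------
# Full pipeline over a simulated study


def default_study_configs(seed: int = 0, n_cohorts: int = 13, n_tumor: int = 200,
                          n_normal: int = 30) -> list[SimConfig]:
    """Configs for the default simulated study.

    Plants: NEIL1 silencing (40% of tumors, 0.2 expression knockdown, +0.4
    beta shift) with a positive mutation-rate coupling in 4 of 13 cohorts;
    a hazard ratio of 2 for the silenced group in the second cohort; a
    shared latent factor tying NEIL3 and APOBEC3B in every cohort; and
    opposite cross-cancer expression gradients for NEIL1 (negative trend
    versus mutation rate) and NEIL3 (positive trend).
    """
    grad = np.linspace(-1.0, 1.0, n_cohorts)
    silenced_cohorts = {0, 1, 2, 3}
    configs = []
    for i in range(n_cohorts):
        base = {"NEIL1": 200.0, "NEIL2": 200.0, "NEIL3": 200.0, "APOBEC3B": 200.0, "YWHAZ": 2000.0}
        # opposite expression gradients; mutation rate follows -grad, so
        # NEIL1 correlates negatively and NEIL3 positively with load
        base["NEIL1"] *= float(np.exp(0.6 * grad[i]))
        base["NEIL3"] *= float(np.exp(-0.6 * grad[i]))
        configs.append(
            SimConfig(
                cancer_label=f"SIM{i + 1:02d}",
                n_tumor=n_tumor,
                n_normal=n_normal,
                base_expression=base,
                silenced_gene="NEIL1",
                silenced_fraction=0.4 if i in silenced_cohorts else 0.0,
                silencing_expression_factor=0.2,
                silenced_beta_shift=0.4,
                base_mutation_rate=100.0 * float(np.exp(-0.6 * grad[i])),
                load_coupling=0.5 if i in silenced_cohorts else 0.0,
                hazard_ratio=2.0 if i == 1 else 1.0,
                coexpression={"NEIL3": 0.4, "APOBEC3B": 0.4},
                seed=seed * 100_003 + i,
            )
        )
    return configs


def run_pipeline(
    out_dir,
    seed: int = 0,
    configs: list[SimConfig] | None = None,
    cohorts: list[CohortBundle] | None = None,
    genes: tuple[str, ...] = ("NEIL1", "NEIL2", "NEIL3"),
    hk_gene: str = "YWHAZ",
    survival_gene: str = "NEIL1",
    coexpression_pair: tuple[str, str] = ("NEIL3", "APOBEC3B"),
    capture_mb: float = DEFAULT_CAPTURE_MB,
    alpha: float = 0.05,
    thresholds: SilencingThresholds | None = None,
) -> dict:
    """Run all five analyses over a cohort panel and write the report.

    Cohorts come from ``cohorts`` if given, else are simulated from
    ``configs`` (default: :func:`default_study_configs` with ``seed``).
    Writes deterministic TSV/JSON tables plus a provenance record echoing
    every threshold used, and returns the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = thresholds or SilencingThresholds()
    if cohorts is None:
        configs = configs or default_study_configs(seed=seed)
        cohorts = [generate_cohort(c) for c in configs]
    rules = {
        "NEIL1": DichotomyRule(gene="NEIL1", direction="reduced"),
        "NEIL2": DichotomyRule(gene="NEIL2", direction="reduced"),
        "NEIL3": DichotomyRule(gene="NEIL3", direction="elevated"),
    }
    errors: list[dict] = []

    # stage 1: cross-cancer correlations
    cross_rows = []
    medians_tables = {}
    for gene in genes:
        for load_type in ("total", "snp"):
            try:
                corr, medians = stage_cross_cancer(cohorts, gene, hk_gene, load_type, capture_mb)
                cross_rows.append(
                    {"gene": gene, "load_type": load_type, "rho": corr.rho,
                     "p_value": corr.p_value, "n_cohorts": corr.n,
                     "significant": corr.p_value < alpha}
                )
                medians_tables[f"{gene}_{load_type}"] = medians
            except GlycoburdenError as exc:
                errors.append({"stage": "cross_cancer", "gene": gene, "error": str(exc)})
    cross_table = pd.DataFrame(cross_rows)

    # stage 2: per-cohort dichotomized load associations
    assoc_rows = []
    for gene in genes:
        rule = rules.get(gene, DichotomyRule(gene=gene, direction="reduced"))
        for c in cohorts:
            try:
                assoc_rows.append(stage_dichotomized_association(c, gene, rule, "total", capture_mb, alpha))
            except GlycoburdenError as exc:
                errors.append({"stage": "association", "cohort": c.cancer_label,
                               "gene": gene, "error": str(exc)})
    assoc_table = pd.DataFrame(assoc_rows)

    # stage 3: silencing screen
    decisions = []
    for gene in genes:
        for c in cohorts:
            try:
                probe = select_probe(c.methylation, c.expression, gene)
                decisions.append(
                    evaluate_silencing(c.methylation, c.expression, gene, probe,
                                       thresholds=th, cancer_label=c.cancer_label)
                )
            except GlycoburdenError as exc:
                errors.append({"stage": "silencing", "cohort": c.cancer_label,
                               "gene": gene, "error": str(exc)})

    # stage 4: survival on the survival gene
    surv_rows = []
    for c in cohorts:
        try:
            fit = stage_survival(c, survival_gene, rules.get(survival_gene,
                                 DichotomyRule(gene=survival_gene, direction="reduced")), alpha=alpha)
            cox_row = fit.cox.loc["abnormal"]
            multi_row = fit.extras["multivariate"].loc["abnormal"]
            surv_rows.append(
                {"cancer_label": c.cancer_label, "gene": survival_gene,
                 "n_abnormal": fit.extras["n_abnormal"], "n_other": fit.extras["n_other"],
                 "logrank_chi2": fit.logrank_chi2, "logrank_p": fit.logrank_p,
                 "hr": cox_row["hr"], "ci_low": cox_row["ci_low"], "ci_high": cox_row["ci_high"],
                 "cox_p": cox_row["p_value"], "hr_multivariate": multi_row["hr"],
                 "significant": fit.logrank_p < alpha, "converged": fit.converged}
            )
        except GlycoburdenError as exc:
            errors.append({"stage": "survival", "cohort": c.cancer_label, "error": str(exc)})
    surv_table = pd.DataFrame(surv_rows)

    # stage 5: co-expression screen
    co_rows = []
    gene_a, gene_b = coexpression_pair
    for c in cohorts:
        try:
            co_rows.append(
                stage_coexpression(c, gene_a, gene_b,
                                   rules.get(gene_a, DichotomyRule(gene=gene_a, direction="elevated")),
                                   alpha=alpha)
            )
        except GlycoburdenError as exc:
            errors.append({"stage": "coexpression", "cohort": c.cancer_label, "error": str(exc)})
    co_table = pd.DataFrame(co_rows)

    provenance = {
        "seed": seed,
        "alpha": alpha,
        "capture_mb": capture_mb,
        "hk_gene": hk_gene,
        "genes": list(genes),
        "survival_gene": survival_gene,
        "coexpression_pair": list(coexpression_pair),
        "thresholds": dataclasses.asdict(th),
        "dichotomy_rules": {g: dataclasses.asdict(r) for g, r in rules.items()},
        "n_cohorts": len(cohorts),
        "cohort_labels": [c.cancer_label for c in cohorts],
    }
    write_report(cross_table, out / "cross_cancer.tsv", "tsv")
    write_report(assoc_table, out / "association.tsv", "tsv")
    write_report(surv_table, out / "survival.tsv", "tsv")
    write_report(co_table, out / "coexpression.tsv", "tsv")
    write_report(
        {f"{d.cancer_label}:{d.gene}": d for d in decisions},
        out / "silencing.json",
        "json",
    )
    with (out / "provenance.json").open("w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_report({"errors": errors}, out / "errors.json", "json")
    return {
        "cross_cancer": cross_table,
        "association": assoc_table,
        "silencing": decisions,
        "survival": surv_table,
        "coexpression": co_table,
        "medians": medians_tables,
        "errors": errors,
        "provenance": provenance,
    }
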