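"""Four-criterion promoter-hypermethylation silencing classifier.

A gene is called epigenetically silenced in a cohort when, at a CpG probe
near its transcription start site, all four of the following hold:

1. mean beta in normal tissue < 0.4 (the promoter is unmethylated in
   normal tissue);
2. (90th percentile of tumor beta) - (mean normal beta) > 0.1 (a tumor
   subset gains methylation);
3. (mean expression in normal tissue) / (mean expression of the 10% of
   tumors with the highest beta) > 1.5 (the hypermethylated tumors lose
   expression);
4. Spearman rho between beta and expression < -0.25 (methylation and
   expression are inversely coupled).

The classifier also reports the hypermethylated-tumor percentage: the share
of tumors whose beta exceeds the normal mean by more than 0.15.

Criterion 4 is computed over tumor and normal samples jointly by default
(both tissues carry signal for the inverse coupling); a tumors-only mode is
available.  Expression enters criteria 3-4 raw, not housekeeping-normalized:
the coupling of interest is between methylation and the gene's own level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import ExpressionMatrix, MethylationTable
from .stats_core import spearman


@dataclass
class SilencingThresholds:
    """Thresholds of the four criteria plus reporting knobs.

    ``top_beta_fraction`` is the tumor fraction (ranked by beta) whose mean
    expression forms criterion 3's denominator; ``tumor_beta_percentile``
    the percentile in criterion 2; ``hypermethylation_delta`` the beta
    excess over the normal mean that marks a tumor as hypermethylated.
    """

    normal_beta_max: float = 0.4
    delta_beta_min: float = 0.1
    fold_change_min: float = 1.5
    rho_max: float = -0.25
    hypermethylation_delta: float = 0.15
    top_beta_fraction: float = 0.10
    tumor_beta_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.top_beta_fraction < 1:
            raise DataError("top_beta_fraction must be in (0, 1)")
        if not 0 < self.tumor_beta_percentile < 100:
            raise DataError("tumor_beta_percentile must be in (0, 100)")


@dataclass
class SilencingDecision:
    cancer_label: str
    gene: str
    probe_id: str
    normal_mean_beta: float | None
    delta_beta: float | None
    fold_change: float | None
    rho: float | None
    rho_p: float | None
    criterion_flags: dict = field(default_factory=dict)
    silenced: bool = False
    hypermethylated_tumor_pct: float = float("nan")
    n_normal_meth: int = 0
    n_tumor_meth: int = 0
    n_pairs_expr: int = 0
    fallback_used: bool = False


def criteria_from_summary(
    delta_beta: float,
    fold_change: float,
    rho: float,
    thresholds: SilencingThresholds | None = None,
) -> dict[str, bool]:
    """Apply criteria 2-4 to pre-computed summary values.

    Useful for checking published per-cohort summaries (delta beta, fold
    change, rho) against the thresholds without the sample-level data.
    """
    th = thresholds or SilencingThresholds()
    return {
        "delta_beta": delta_beta > th.delta_beta_min,
        "fold_change": fold_change > th.fold_change_min,
        "rho": rho < th.rho_max,
    }


def select_probe(
    meth: MethylationTable,
    expr: ExpressionMatrix,
    gene: str,
    tss_window_bp: int = 1500,
    configured: str | None = None,
) -> str:
    """Pick the CpG probe used for a gene's silencing call.

    A configured probe ID wins when present.  Otherwise, among annotated
    probes within ``tss_window_bp`` of the TSS, pick the one whose beta is
    most negatively rank-correlated with the gene's expression; ties break
    lexicographically by probe ID.
    """
    if configured is not None:
        if configured not in meth.beta.index:
            raise DataError(f"configured probe {configured!r} not in methylation table")
        return configured
    candidates = meth.probes_for_gene(gene, tss_window_bp)
    if not candidates:
        raise DataError(f"no probe for {gene!r} within {tss_window_bp} bp of the TSS")
    if len(candidates) == 1:
        return candidates[0]
    scored = []
    for probe in sorted(candidates):
        beta, ex = _paired_beta_expression(meth, expr, gene, probe, tissues=("tumor", "normal"))
        try:
            rho = spearman(beta, ex).rho
        except Exception:
            rho = float("inf")  # uncorrelatable probes lose
        scored.append((rho, probe))
    return min(scored)[1]


def _paired_beta_expression(meth, expr, gene, probe, tissues) -> tuple[np.ndarray, np.ndarray]:
    beta_row = meth.beta.loc[probe]
    samples = [
        s
        for s in beta_row.index
        if meth.tissue[s] in tissues and s in expr.values.columns and not math.isnan(beta_row[s])
    ]
    beta = beta_row[samples].to_numpy(float)
    ex = expr.values.loc[gene, samples].to_numpy(float)
    return beta, ex


def hypermethylated_fraction(
    meth: MethylationTable,
    probe: str,
    delta: float = 0.15,
    fallback_normal_mean: float | None = None,
) -> float:
    """Percent of tumors with beta exceeding the normal mean beta + delta."""
    row = meth.beta.loc[probe]
    tumors = row[meth.sample_ids("tumor")].dropna()
    if len(tumors) == 0:
        raise DataError("no tumor beta values")
    normals = row[meth.sample_ids("normal")].dropna()
    if len(normals) > 0:
        normal_mean = float(normals.mean())
    elif fallback_normal_mean is not None:
        normal_mean = float(fallback_normal_mean)
    else:
        raise DataError("no normal beta values and no fallback mean supplied")
    return 100.0 * float((tumors > normal_mean + delta).sum()) / len(tumors)


def evaluate_silencing(
    meth: MethylationTable,
    expr: ExpressionMatrix,
    gene: str,
    probe: str,
    thresholds: SilencingThresholds | None = None,
    cancer_label: str = "",
    tumors_only_rho: bool = False,
    min_tumors: int = 10,
    fallback_normal_expr_mean: float | None = None,
    fallback_normal_beta_mean: float | None = None,
) -> SilencingDecision:
    """Evaluate the four silencing criteria for one (cohort, gene, probe).

    Requires >= 2 normal methylation samples (or ``fallback_normal_beta_mean``)
    and >= ``min_tumors`` tumors carrying both beta and expression.  When a
    cohort lacks normal expression columns, ``fallback_normal_expr_mean``
    (e.g. a normal-tissue mean taken from an external cohort of the same
    organ) substitutes in criterion 3 and the decision is flagged.
    """
    th = thresholds or SilencingThresholds()
    if gene not in expr.values.index:
        raise DataError(f"gene {gene!r} not in expression matrix")
    if probe not in meth.beta.index:
        raise DataError(f"probe {probe!r} not in methylation table")
    row = meth.beta.loc[probe]

    normal_beta = row[meth.sample_ids("normal")].dropna()
    fallback_used = False
    if len(normal_beta) >= 2:
        normal_mean_beta = float(normal_beta.mean())
    elif fallback_normal_beta_mean is not None:
        normal_mean_beta = float(fallback_normal_beta_mean)
        fallback_used = True
    else:
        raise DataError("need >= 2 normal methylation samples or a fallback beta mean")

    tumor_beta_all = row[meth.sample_ids("tumor")].dropna()
    # tumors carrying both layers drive criteria 3-4
    tumor_both = tumor_beta_all[[s for s in tumor_beta_all.index if s in expr.values.columns]]
    if len(tumor_both) < min_tumors:
        raise DataError(
            f"need >= {min_tumors} tumors with both beta and expression, got {len(tumor_both)}"
        )

    delta_beta = float(
        np.percentile(tumor_beta_all.to_numpy(), th.tumor_beta_percentile) - normal_mean_beta
    )

    # criterion 3: normal-mean expression over mean expression of the
    # top-beta tumor slice; k = ceil(fraction * n), beta ties broken by ID
    expr_normals = [s for s in expr.normal_samples]
    if fallback_normal_expr_mean is not None:  # an explicitly supplied mean wins
        normal_expr_mean = float(fallback_normal_expr_mean)
        fallback_used = True
    elif expr_normals:
        normal_expr_mean = float(expr.values.loc[gene, expr_normals].mean())
    else:
        raise DataError("no normal expression samples and no fallback mean supplied")
    k = math.ceil(th.top_beta_fraction * len(tumor_both))
    ranked = tumor_both.reset_index()
    ranked.columns = ["sample", "beta"]
    ranked = ranked.sort_values(["beta", "sample"], ascending=[False, True])
    top_samples = list(ranked["sample"].iloc[:k])
    top_expr_mean = float(expr.values.loc[gene, top_samples].mean())
    if top_expr_mean == 0:
        raise DataError("mean expression of the top-beta tumors is 0: fold change undefined")
    fold_change = normal_expr_mean / top_expr_mean

    tissues = ("tumor",) if tumors_only_rho else ("tumor", "normal")
    beta_pairs, expr_pairs = _paired_beta_expression(meth, expr, gene, probe, tissues)
    corr = spearman(beta_pairs, expr_pairs)

    flags = {
        "normal_beta": normal_mean_beta < th.normal_beta_max,
        "delta_beta": delta_beta > th.delta_beta_min,
        "fold_change": fold_change > th.fold_change_min,
        "rho": corr.rho < th.rho_max,
    }
    pct = hypermethylated_fraction(
        meth,
        probe,
        delta=th.hypermethylation_delta,
        fallback_normal_mean=normal_mean_beta,
    )
    return SilencingDecision(
        cancer_label=cancer_label,
        gene=gene,
        probe_id=probe,
        normal_mean_beta=normal_mean_beta,
        delta_beta=delta_beta,
        fold_change=fold_change,
        rho=corr.rho,
        rho_p=corr.p_value,
        criterion_flags=flags,
        silenced=all(flags.values()),
        hypermethylated_tumor_pct=pct,
        n_normal_meth=len(normal_beta),
        n_tumor_meth=len(tumor_beta_all),
        n_pairs_expr=corr.n,
        fallback_used=fallback_used,
    )


def evaluate_silencing_fallback(
    meth: MethylationTable,
    expr: ExpressionMatrix,
    gene: str,
    probe: str,
    normal_expr_mean: float,
    normal_beta_mean: float | None = None,
    **kwargs,
) -> SilencingDecision:
    """Silencing call for a cohort without its own normal reference tissue.

    ``normal_expr_mean`` (mandatory) substitutes the normal expression mean
    in criterion 3; ``normal_beta_mean`` substitutes the normal beta mean in
    criteria 1-2 when the cohort also lacks normal methylation columns.  The
    returned decision is flagged ``fallback_used``.
    """
    if normal_expr_mean is None:
        raise DataError("fallback requires an external normal expression mean")
    decision = evaluate_silencing(
        meth,
        expr,
        gene,
        probe,
        fallback_normal_expr_mean=float(normal_expr_mean),
        fallback_normal_beta_mean=normal_beta_mean,
        **kwargs,
    )
    decision.fallback_used = True
    return decision
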