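"""The four-criterion silencing classifier and its helpers."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from glycoburden.errors import DataError
from glycoburden.io_formats import ExpressionMatrix, MethylationTable
from glycoburden.silencing import (
    SilencingThresholds,
    criteria_from_summary,
    evaluate_silencing,
    evaluate_silencing_fallback,
    hypermethylated_fraction,
    select_probe,
)
from glycoburden.synthetic_data import SimConfig, generate_cohort


def _meth(beta_rows, tissue, annotation_rows):
    beta = pd.DataFrame(beta_rows).T if isinstance(beta_rows, dict) else beta_rows
    ann = pd.DataFrame(
        annotation_rows, columns=["probe_id", "gene_symbol", "tss_distance"]
    ).set_index("probe_id")
    return MethylationTable(beta=beta, annotation=ann, tissue=pd.Series(tissue))


class TestSelectProbe:
    def test_single_probe_forced(self, null_cohort):
        meth, expr = null_cohort.methylation, null_cohort.expression
        probes = meth.probes_for_gene("NEIL1")
        assert select_probe(meth, expr, "NEIL1") == probes[0]

    def test_configured_probe_wins(self, null_cohort):
        meth, expr = null_cohort.methylation, null_cohort.expression
        configured = meth.probes_for_gene("NEIL3")[0]
        assert select_probe(meth, expr, "NEIL1", configured=configured) == configured

    def test_most_anticorrelated_probe_chosen(self):
        rng = np.random.default_rng(21)
        n = 40
        samples = [f"P-T{i:02d}-01A" for i in range(n)]
        expr_vals = rng.lognormal(3, 0.3, n)
        # probe A tracks expression inversely; probe B is pure noise
        beta_a = np.clip(0.8 - 0.1 * (expr_vals - expr_vals.mean()) / expr_vals.std(), 0, 1)
        beta_b = rng.uniform(0.2, 0.4, n)
        meth = _meth(
            pd.DataFrame([beta_a, beta_b], index=["cg0000000A", "cg0000000B"], columns=samples),
            {s: "tumor" for s in samples},
            [("cg0000000A", "G", 50), ("cg0000000B", "G", 80)],
        )
        expr = ExpressionMatrix(
            values=pd.DataFrame([expr_vals], index=["G"], columns=samples),
            tissue=pd.Series({s: "tumor" for s in samples}),
        )
        assert select_probe(meth, expr, "G") == "cg0000000A"

    def test_no_probe_in_window_errors(self, null_cohort):
        with pytest.raises(DataError, match="probe"):
            select_probe(null_cohort.methylation, null_cohort.expression, "NEIL1", tss_window_bp=1)


class TestHypermethylatedFraction:
    def _table(self, tumors, normals=(0.2, 0.2)):
        cols = [f"T{i}-01A" for i in range(len(tumors))] + [f"N{i}-11A" for i in range(len(normals))]
        beta = pd.DataFrame([list(tumors) + list(normals)], index=["cg1"], columns=cols)
        ann = [("cg1", "G", 0)]
        tissue = {c: ("tumor" if "T" in c.split("-")[0] else "normal") for c in cols}
        return _meth(beta, tissue, ann)

    def test_arithmetic(self):
        meth = self._table([0.1, 0.4, 0.5])
        # threshold 0.2 + 0.15 = 0.35 -> 2 of 3 tumors
        assert hypermethylated_fraction(meth, "cg1") == pytest.approx(100 * 2 / 3)

    def test_floor_and_ceiling(self):
        assert hypermethylated_fraction(self._table([0.1, 0.2]), "cg1") == 0.0
        assert hypermethylated_fraction(self._table([0.9, 0.99]), "cg1") == 100.0

    def test_duplication_invariance(self):
        base = hypermethylated_fraction(self._table([0.1, 0.4, 0.5]), "cg1")
        doubled = hypermethylated_fraction(self._table([0.1, 0.4, 0.5] * 2), "cg1")
        assert base == doubled

    def test_no_normals_needs_fallback(self):
        meth = self._table([0.4], normals=())
        with pytest.raises(DataError, match="fallback"):
            hypermethylated_fraction(meth, "cg1")
        assert hypermethylated_fraction(meth, "cg1", fallback_normal_mean=0.2) == 100.0


class TestEvaluateSilencing:
    def test_planted_cohort_called_silenced(self, planted_cohort):
        meth, expr = planted_cohort.methylation, planted_cohort.expression
        probe = select_probe(meth, expr, "NEIL1")
        d = evaluate_silencing(meth, expr, "NEIL1", probe, cancer_label="PLNT")
        assert d.silenced
        assert all(d.criterion_flags.values())
        # beta shift of the planted half should push the 90th percentile up
        assert d.delta_beta > 0.3
        assert d.fold_change > 1.5 and d.rho < -0.25

    def test_null_cohort_not_silenced(self, null_cohort):
        meth, expr = null_cohort.methylation, null_cohort.expression
        probe = select_probe(meth, expr, "NEIL1")
        d = evaluate_silencing(meth, expr, "NEIL1", probe, cancer_label="NULL")
        assert not d.silenced

    def test_unshifted_gene_not_silenced_in_planted_cohort(self, planted_cohort):
        meth, expr = planted_cohort.methylation, planted_cohort.expression
        probe = select_probe(meth, expr, "NEIL2")
        assert not evaluate_silencing(meth, expr, "NEIL2", probe).silenced

    def test_silenced_iff_all_flags(self, planted_cohort, null_cohort):
        for cohort in (planted_cohort, null_cohort):
            meth, expr = cohort.methylation, cohort.expression
            for gene in ("NEIL1", "NEIL2", "NEIL3"):
                d = evaluate_silencing(meth, expr, gene, select_probe(meth, expr, gene))
                assert d.silenced == all(d.criterion_flags.values())
                assert 0.0 <= d.hypermethylated_tumor_pct <= 100.0

    def test_threshold_monotonicity(self, planted_cohort):
        """Hardening any threshold never turns a non-silenced call silenced."""
        meth, expr = planted_cohort.methylation, planted_cohort.expression
        probe = select_probe(meth, expr, "NEIL1")
        default = SilencingThresholds()
        harder_sets = [
            dataclasses.replace(default, normal_beta_max=0.15),
            dataclasses.replace(default, delta_beta_min=0.45),
            dataclasses.replace(default, fold_change_min=8.0),
            dataclasses.replace(default, rho_max=-0.9),
        ]
        for gene in ("NEIL1", "NEIL2", "NEIL3"):
            base = evaluate_silencing(meth, expr, gene, probe, thresholds=default).silenced
            for th in harder_sets:
                hard = evaluate_silencing(meth, expr, gene, probe, thresholds=th).silenced
                assert not (hard and not base)

    def test_too_few_tumors_errors(self):
        cfg = SimConfig(n_tumor=5, n_normal=5, seed=3)
        b = generate_cohort(cfg)
        probe = b.methylation.probes_for_gene("NEIL1")[0]
        with pytest.raises(DataError, match="tumors"):
            evaluate_silencing(b.methylation, b.expression, "NEIL1", probe)


class TestCriteriaFromSummary:
    def test_published_row_passes(self):
        # head-and-neck cohort summary: delta 0.323, fold 2.354, rho -0.3699
        flags = criteria_from_summary(0.323, 2.354, -0.3699)
        assert all(flags.values())

    def test_null_summary_fails_delta(self):
        flags = criteria_from_summary(0.0, 1.0, 0.0)
        assert not any(flags.values())


class TestFallback:
    @staticmethod
    def _strip_normal_expression(cohort):
        expr = cohort.expression
        tumors = expr.tumor_samples
        return ExpressionMatrix(
            values=expr.values[tumors].copy(), tissue=expr.tissue[tumors].copy()
        )

    def test_fallback_cohort_flagged(self, planted_cohort):
        meth = planted_cohort.methylation
        expr_t = self._strip_normal_expression(planted_cohort)
        probe = meth.probes_for_gene("NEIL1")[0]
        full_expr = planted_cohort.expression
        normal_mean = float(full_expr.values.loc["NEIL1", full_expr.normal_samples].mean())
        d = evaluate_silencing_fallback(meth, expr_t, "NEIL1", probe, normal_expr_mean=normal_mean)
        assert d.fallback_used and d.silenced

    def test_fallback_equal_mean_matches_standard_path(self, planted_cohort):
        meth, expr = planted_cohort.methylation, planted_cohort.expression
        probe = meth.probes_for_gene("NEIL1")[0]
        standard = evaluate_silencing(meth, expr, "NEIL1", probe)
        normal_mean = float(expr.values.loc["NEIL1", expr.normal_samples].mean())
        via_fallback = evaluate_silencing_fallback(
            meth, expr, "NEIL1", probe, normal_expr_mean=normal_mean
        )
        assert via_fallback.fold_change == pytest.approx(standard.fold_change)
        assert via_fallback.silenced == standard.silenced

    def test_no_normals_no_fallback_errors(self, planted_cohort):
        meth = planted_cohort.methylation
        expr_t = self._strip_normal_expression(planted_cohort)
        probe = meth.probes_for_gene("NEIL1")[0]
        with pytest.raises(DataError, match="fallback"):
            evaluate_silencing(meth, expr_t, "NEIL1", probe)
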