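"""Rank and survival statistics against hand calculations and scipy/lifelines."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from glycoburden.errors import StatError
from glycoburden.stats_core import (
    cox_ph,
    km_curve,
    km_logrank,
    mann_whitney_u,
    spearman,
    wilcoxon_signed_rank,
)
from glycoburden.io_formats import SurvivalRecord


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)

    def test_derived_example(self):
        # d^2 = 6 -> rho = 1 - 6*6/(3*8) = -0.5
        assert spearman([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(StatError, match="constant"):
            spearman([1, 2, 3], [5, 5, 5])

    def test_too_few_pairs_errors(self):
        with pytest.raises(StatError):
            spearman([1, 2], [2, 1])

    def test_nan_pairs_removed(self):
        r = spearman([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert r.n == 3 and r.rho == pytest.approx(1.0)

    def test_matches_scipy_at_moderate_n(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        ours = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(5), rng.standard_normal(5)
        ours = spearman(x, y)  # auto -> exact at n=5
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, p)[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(ry)
        )
        assert ours.p_value == pytest.approx(hits / math.factorial(5))


class TestMannWhitney:
    def test_identical_groups_are_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(a, a)
        assert r.u_statistic == pytest.approx(len(a) ** 2 / 2)
        assert r.p_value >= 0.99
        assert r.direction == "none"

    def test_complete_separation_exact_p(self):
        # enumerate all C(4,2)=6 labelings: U=0 gives two-sided P = 1/3
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.u_statistic == 0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(1 / 3)

    def test_tie_saturation(self):
        r = mann_whitney_u([5.0] * 3, [5.0] * 4)
        assert r.u_statistic == pytest.approx(3 * 4 / 2)
        assert r.direction == "none" and r.p_value == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(StatError):
            mann_whitney_u([], [1.0])

    def test_direction_follows_medians(self):
        rng = np.random.default_rng(2)
        low = rng.normal(0, 1, 60)
        high = rng.normal(2, 1, 60)
        assert mann_whitney_u(low, high).direction == "increase"
        assert mann_whitney_u(high, low).direction == "decrease"

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for n_a, n_b in [(3, 4), (5, 5), (2, 6)]:
            a, b = rng.standard_normal(n_a), rng.standard_normal(n_b)
            ours = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approx_close_to_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 8, 40).astype(float)
        b = rng.integers(1, 9, 35).astype(float)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestWilcoxon:
    def test_all_zero_diffs_degenerate(self):
        with pytest.raises(StatError, match="degenerate"):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_three_positive_diffs(self):
        # 2^3 sign patterns; one-tail P = 1/8, two-sided = 0.25
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(0.25)

    def test_symmetric_pair_is_null(self):
        r = wilcoxon_signed_rank([5.0, -5.0])
        assert r.p_value == 1.0

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestKaplanMeierLogrank:
    def test_product_limit_arithmetic(self):
        curve = km_curve([1.0, 2.0], [True, True])
        assert curve["survival"].tolist() == pytest.approx([0.5, 0.0])

    def test_curves_non_increasing_and_start_below_one(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        s = km_curve(t, e)["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12) and s[0] <= 1.0

    def test_duplicated_group_gives_zero_chi2(self):
        g = [SurvivalRecord(f"S{i}", t, ev) for i, (t, ev) in enumerate([(1, 1), (2, 1), (3, 0)])]
        fit = km_logrank({"a": g, "b": list(g)})
        assert fit.logrank_chi2 == 0.0 and fit.logrank_p == 1.0

    def test_hand_tabulated_two_group_logrank(self):
        # A: events at 1, 2; B: events at 3, 4 (no censoring).
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (2 - 5/6)^2 / (17/36) = 2.88235...
        a = [SurvivalRecord("a1", 1, True), SurvivalRecord("a2", 2, True)]
        b = [SurvivalRecord("b1", 3, True), SurvivalRecord("b2", 4, True)]
        fit = km_logrank({"a": a, "b": b})
        assert fit.logrank_chi2 == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36))

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(9)
        t1, t2 = rng.exponential(10, 40), rng.exponential(14, 45)
        e1, e2 = rng.random(40) < 0.8, rng.random(45) < 0.8
        fit = km_logrank(
            {
                "a": [SurvivalRecord(f"a{i}", t, ev) for i, (t, ev) in enumerate(zip(t1, e1))],
                "b": [SurvivalRecord(f"b{i}", t, ev) for i, (t, ev) in enumerate(zip(t2, e2))],
            }
        )
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert fit.logrank_chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert fit.logrank_p == pytest.approx(ref.p_value, rel=1e-6)

    def test_no_events_errors(self):
        g1 = [SurvivalRecord("a", 1.0, False)]
        g2 = [SurvivalRecord("b", 2.0, False)]
        with pytest.raises(StatError, match="events"):
            km_logrank({"a": g1, "b": g2})


class TestCox:
    @staticmethod
    def _simulate(n, beta, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        z = rng.standard_normal(n)
        lam = 0.01 * np.exp(beta * x + 0.3 * z)
        death = rng.exponential(1 / lam)
        censor = rng.exponential(300, n)
        import pandas as pd

        return pd.DataFrame(
            {
                "time": np.minimum(death, censor),
                "event": death <= censor,
                "x": x,
                "z": z,
            }
        )

    def test_matches_lifelines_breslow(self):
        from lifelines import CoxPHFitter

        df = self._simulate(200, math.log(2), seed=10)
        ours = cox_ph(df, ["x", "z"])
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        for cov in ("x", "z"):
            assert ours.cox.loc[cov, "coef"] == pytest.approx(
                cph.params_[cov], abs=5e-3
            )
            assert ours.cox.loc[cov, "se"] == pytest.approx(
                cph.standard_errors_[cov], abs=5e-3
            )

    def test_planted_hr_recovered(self):
        df = self._simulate(500, math.log(2), seed=0)
        fit = cox_ph(df, ["x", "z"])  # the generating model: x effect + z effect
        row = fit.cox.loc["x"]
        assert row["ci_low"] < 2.0 < row["ci_high"]
        assert fit.converged

    def test_constant_covariate_errors(self):
        df = self._simulate(50, 0.0, seed=12)
        df["c"] = 1.0
        with pytest.raises(StatError, match="constant"):
            cox_ph(df, ["c"])

    def test_no_events_errors(self):
        df = self._simulate(50, 0.0, seed=13)
        df["event"] = False
        with pytest.raises(StatError, match="events"):
            cox_ph(df, ["x"])

    def test_efron_close_to_breslow_without_ties(self):
        df = self._simulate(120, 0.5, seed=14)
        b = cox_ph(df, ["x"], ties="breslow")
        e = cox_ph(df, ["x"], ties="efron")
        assert b.cox.loc["x", "coef"] == pytest.approx(e.cox.loc["x", "coef"], abs=1e-9)


@given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=9, unique=True))
def test_spearman_bounded_and_symmetric(xs):
    ys = list(reversed(xs))
    r = spearman(xs, ys)
    assert -1.0 <= r.rho <= 1.0
    assert 0.0 < r.p_value <= 1.0
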