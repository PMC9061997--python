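"""Kaplan-Meier, log-rank, Cox partial likelihood, and contingency tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from icpattern import contingency_test, cox_fit, km_estimate, logrank_test, \
    univariate_screen
from icpattern.io import ExpressionMatrix


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(km.at_risk, [4, 3, 2, 1])

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(99.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        """times [1, 2+, 3]: stepwise hand product-limit gives
        S(1) = (1 - 1/3) = 2/3 and S(3) = (2/3)(1 - 1/1) = 0, since the
        subject censored at 2 has left the risk set before the event at 3."""
        km = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        # censored-at-event-time convention: censoring at t counts as at risk
        km2 = km_estimate([1, 2, 2, 3], [1, 1, 0, 1])
        np.testing.assert_allclose(km2.at_risk, [4, 3, 1])
        np.testing.assert_allclose(km2.survival, [3 / 4, 3 / 4 * 2 / 3, 0.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, size=200)
        e = (rng.uniform(size=200) < 0.6).astype(int)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (km.survival >= 0).all() and (km.survival <= 1).all()
        assert (km.greenwood_var >= 0).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = np.maximum(rng.exponential(5, size=150), 1e-3)
        e = (rng.uniform(size=150) < 0.7).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tj, s in zip(km.times, km.survival):
            assert kmf.predict(tj) == pytest.approx(s, abs=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4, 5.0] * 2
        e = [1, 0, 1, 1, 0] * 2
        g = [0] * 5 + [1] * 5
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert np.sum(res.observed - res.expected) == pytest.approx(0.0, abs=1e-12)

    def test_six_subject_toy_against_hand_aggregation_and_permutations(self):
        """A events at 1,3,5; B at 2,4,6 — O/E/V by hand; p vs all 20 relabelings."""
        times = np.array([1, 2, 3, 4, 5, 6.0])
        events = np.ones(6, dtype=int)
        groups = np.array([0, 1, 0, 1, 0, 1])
        res = logrank_test(times, events, groups)
        # hand: at t=1..6, group-0 at-risk 3,2,2,1,1,0 of N=6..1
        e0 = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2 + 0 / 1
        assert res.expected[0] == pytest.approx(e0)
        assert res.observed[0] == 3
        v = sum(n0 / n * (1 - n0 / n) for n0, n in
                [(3, 6), (2, 5), (2, 4), (1, 3), (1, 2), (0, 1)])
        assert res.variance[0, 0] == pytest.approx(v)
        stat_obs = res.statistic
        perm_stats = []
        for idx in combinations(range(6), 3):
            g = np.zeros(6, dtype=int)
            g[list(idx)] = 1
            perm_stats.append(logrank_test(times, events, g).statistic)
        p_perm = np.mean(np.asarray(perm_stats) >= stat_obs - 1e-12)
        assert abs(res.p_value - p_perm) < 0.15

    def test_matches_lifelines_multigroup(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(2)
        t = np.maximum(rng.exponential(3, size=90), 1e-3)
        e = (rng.uniform(size=90) < 0.7).astype(int)
        g = rng.integers(0, 3, size=90)
        res = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2.0], [1, 1], [0, 0])


def cox_grid_oracle(times, events, x):
    """1-d Breslow partial log-likelihood maximized by golden-section search."""
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    order = np.argsort(times)
    times, x = times[order], x[order]
    ev = np.asarray(events)[order].astype(bool)

    def pll(beta):
        eta = beta * x
        ll = 0.0
        for i in np.flatnonzero(ev):
            risk = times >= times[i]
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
        return ll

    grid = np.linspace(-3, 3, 2001)
    vals = [pll(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCox:
    def test_recovers_true_hazard_ratio_and_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 400
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2) * x)))
        df = pd.DataFrame({"os_time": t, "os_event": 1, "x": x})
        res = cox_fit(df, ["x"])
        assert abs(res.beta["x"] - np.log(2)) < 3 * res.se["x"]
        assert res.beta["x"] == pytest.approx(
            cox_grid_oracle(t, np.ones(n), x), abs=5e-3)
        assert res.ci_lower["x"] < res.hazard_ratio["x"] < res.ci_upper["x"]

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))  # continuous: no ties
        df = pd.DataFrame({"os_time": np.maximum(t, 1e-9), "os_event": 1, "x": x})
        efron = cox_fit(df, ["x"], ties="efron")
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert efron.beta["x"] == pytest.approx(breslow.beta["x"], abs=1e-8)

    def test_score_statistic_identity_with_logrank(self):
        """Cox score test at beta=0 for a binary covariate equals the log-rank
        chi-square (tie-free data)."""
        rng = np.random.default_rng(5)
        n = 80
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(np.exp(-0.8 * x))
        lr = logrank_test(t, np.ones(n, dtype=int), x)
        # score U and information I at beta=0 computed directly
        order = np.argsort(t)
        ts, xs = t[order], x[order].astype(float)
        U = I = 0.0
        for i in range(n):
            risk = ts >= ts[i]
            m = xs[risk].mean()
            U += xs[i] - m
            I += (xs[risk] ** 2).mean() - m ** 2
        assert U ** 2 / I == pytest.approx(lr.statistic, rel=1e-10)

    def test_constant_covariate_named_in_error(self):
        df = pd.DataFrame({"os_time": [1, 2, 3, 4.0], "os_event": [1, 1, 0, 1],
                           "flat": 1.0, "x": [0, 1, 0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["flat", "x"])

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        df = pd.DataFrame({"os_time": rng.exponential(1, 50), "os_event": 1,
                           "x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            cox_fit(df, ["x1", "x2"])

    def test_separation_flagged(self):
        # binary covariate perfectly separates early from late events:
        # monotone partial likelihood, diverging coefficient
        n = 30
        x = np.repeat([0.0, 1.0], n // 2)
        t = np.concatenate([np.arange(16.0, 31.0), np.arange(1.0, 16.0)])
        df = pd.DataFrame({"os_time": t, "os_event": 1, "x": x})
        with pytest.warns(UserWarning, match="separation"):
            res = cox_fit(df, ["x"])
        assert not res.converged


class TestUnivariateScreen:
    def test_planted_protective_gene_labelled_favorable(self):
        rng = np.random.default_rng(7)
        n = 300
        g = rng.normal(size=n)
        t = np.maximum(rng.exponential(1.0 / (0.05 * np.exp(-0.7 * g))), 1e-6)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        expr = ExpressionMatrix(pd.DataFrame(
            [g, rng.normal(size=n)], index=["prot", "null"],
            columns=[f"S{j}" for j in range(n)]))
        surv = pd.DataFrame({"os_time": t, "os_event": e},
                            index=[f"S{j}" for j in range(n)])
        table = univariate_screen(expr, surv)
        assert table.loc["prot", "direction"] == "favorable"
        assert table.loc["prot", "cox_p"] < 1e-4
        assert np.isfinite(table.loc["null", "logrank_p"])

    def test_constant_gene_gives_missing_row(self):
        rng = np.random.default_rng(8)
        n = 40
        expr = ExpressionMatrix(pd.DataFrame(
            [np.ones(n), rng.normal(size=n)], index=["flat", "ok"],
            columns=[f"S{j}" for j in range(n)]))
        surv = pd.DataFrame({"os_time": rng.exponential(2, n) + 0.01,
                             "os_event": 1}, index=expr.samples)
        with pytest.warns(UserWarning, match="constant"):
            table = univariate_screen(expr, surv)
        assert np.isnan(table.loc["flat", "beta"])
        assert np.isfinite(table.loc["ok", "beta"])


def fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration with fixed margins."""
    a, b, c, d = np.asarray(table).ravel()
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return float(sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs + 1e-12))


class TestContingency:
    def test_perfect_independence(self):
        a = ["x"] * 10 + ["y"] * 10 + ["x"] * 10 + ["y"] * 10
        b = ["u"] * 20 + ["v"] * 20
        res = contingency_test(a, b)
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_diagonal_table_matches_hypergeometric_enumeration(self):
        """[[4,0],[0,4]]: two-sided Fisher p = 2/70."""
        a = ["x"] * 4 + ["y"] * 4
        b = ["u"] * 4 + ["v"] * 4
        res = contingency_test(a, b)
        assert res.p_value == pytest.approx(2 / 70)
        assert res.p_value == pytest.approx(fisher_oracle([[4, 0], [0, 4]]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_2x2_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.choice(["x", "y"], size=30)
        b = rng.choice(["u", "v"], size=30)
        res = contingency_test(a, b)
        table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
        assert res.p_value == pytest.approx(fisher_oracle(table), abs=1e-9)

    def test_larger_table_uses_chi_square(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["x", "y", "z"], size=90)
        b = rng.choice(["u", "v", "w"], size=90)
        res = contingency_test(a, b)
        assert res.method == "chi2"
        assert res.df == 4

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 nonempty levels"):
            contingency_test(["x"] * 10, ["u"] * 5 + ["v"] * 5)
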