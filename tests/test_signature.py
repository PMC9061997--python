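"""DEG derivation, the ICscore PCA model, and the survival-optimal cutpoint."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from icpattern import cluster_degs, derive_icscore, dichotomize_by_cutpoint
from icpattern.io import ExpressionMatrix
from icpattern.signature import ICScoreModel


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def bh_oracle(pvals):
    """Step-up formula: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestBenjaminiHochberg:
    def test_worked_example(self):
        """BH on [0.01, 0.02, 0.03, 0.04] gives 0.04 everywhere."""
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=57)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()


class TestClusterDegs:
    def _planted(self, seed=0, n_shift=50, shift=2.0, n_per=80):
        rng = np.random.default_rng(seed)
        n_genes = 300
        vals = rng.normal(size=(n_genes, 3 * n_per))
        labels = pd.Series(np.repeat(["A", "B", "C"], n_per),
                           index=[f"S{j}" for j in range(3 * n_per)])
        # A vs C shifted by +-shift in the first n_shift genes; B halfway
        pat_level = np.repeat([1.0, 0.0, -1.0], n_per)
        vals[:n_shift] += shift / 2.0 * pat_level
        return _expr(vals, samples=list(labels.index)), labels

    def test_planted_shift_recovered_and_intersection_nested(self):
        expr, labels = self._planted()
        res = cluster_degs(expr, labels, fdr_threshold=0.05)
        planted = {f"G{i}" for i in range(50)}
        assert planted <= set(res.significant[("A", "C")])
        for sig in res.significant.values():
            assert set(res.intersection) <= set(sig)

    def test_adjusted_p_dominates_raw(self):
        expr, labels = self._planted(seed=1)
        res = cluster_degs(expr, labels)
        for df in res.contrasts.values():
            assert (df["adj_p"] >= df["p"] - 1e-15).all()
            assert df["adj_p"].between(0, 1).all()

    def test_global_null_discovery_rate_controlled(self):
        """With all groups exchangeable, any-discovery rate stays near alpha."""
        rng = np.random.default_rng(2)
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            vals = rng.normal(size=(1000, 40))
            labels = pd.Series(np.repeat(["A", "B"], 20),
                               index=[f"S{j}" for j in range(40)])
            res = cluster_degs(_expr(vals, samples=list(labels.index)), labels)
            hits += bool(res.significant[("A", "B")])
        rate = hits / n_runs
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_small_group_rejected(self):
        expr, labels = self._planted(n_per=10)
        labels.iloc[:8] = "D"  # leaves A with 2 samples
        with pytest.raises(ValueError, match="fewer than 3"):
            cluster_degs(expr, labels)

    def test_wilcoxon_option(self):
        expr, labels = self._planted(seed=3, n_per=20)
        res = cluster_degs(expr, labels, method="wilcoxon")
        assert set(res.contrasts) == {("A", "B"), ("A", "C"), ("B", "C")}


def icscore_oracle(values):
    """Brute-force eigendecomposition ICscore with the loading-sum sign rule."""
    Z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    C = np.cov(Z, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:2]
    load = V[:, order]
    for j in range(2):
        if load[:, j].sum() > 0:
            load[:, j] = -load[:, j]
    return (Z @ load).sum(axis=1)


class TestICscore:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 50))  # genes x samples
        expr = _expr(vals)
        res = derive_icscore(expr, expr.genes)
        expected = icscore_oracle(vals.T)
        np.testing.assert_allclose(res.scores.to_numpy(), expected, atol=1e-8)

    def test_perfectly_correlated_genes_collapse_to_pc1(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=30)
        expr = _expr(np.vstack([g, 2 * g + 1]))
        res = derive_icscore(expr, expr.genes)
        assert res.model.explained_variance_ratio_[1] == pytest.approx(0.0, abs=1e-12)
        # score equals the oriented PC1 coordinate alone
        z = (g - g.mean()) / g.std(ddof=1)
        pc1 = -np.sqrt(2) * z  # two identical z-scored genes, negative orientation
        np.testing.assert_allclose(res.scores.to_numpy(), pc1, atol=1e-8)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(8, 40))
        expr = _expr(vals)
        s1 = derive_icscore(expr, expr.genes).scores
        s2 = derive_icscore(expr, expr.genes[::-1]).scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_heldout_scoring_consistent_with_joint_fit(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(12, 60))
        expr = _expr(vals)
        res = derive_icscore(expr, expr.genes)
        X = expr.values.T
        held = res.model.transform(X.iloc[40:])
        np.testing.assert_allclose(held.to_numpy(), res.scores.iloc[40:].to_numpy(),
                                   atol=1e-12)

    def test_missing_genes_dropped_with_warning(self):
        expr = _expr(np.random.default_rng(8).normal(size=(5, 20)))
        with pytest.warns(UserWarning, match="not in matrix"):
            res = derive_icscore(expr, expr.genes + ["NOPE"])
        assert len(res.model.genes_) == 5

    def test_too_few_usable_genes_rejected(self):
        expr = _expr(np.random.default_rng(9).normal(size=(5, 10)))
        with pytest.raises(ValueError, match="fewer than 2"):
            derive_icscore(expr, ["G0"])

    def test_loading_sum_orientation(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(6, 30)) + np.linspace(0, 3, 30)
        model = ICScoreModel().fit(_expr(vals).values.T)
        sums = model.loadings_.sum(axis=0)
        assert (sums <= 1e-10).all()


class TestCutpoint:
    def _toy(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.normal(size=60), index=[f"S{j}" for j in range(60)])
        risk = (scores > 0).astype(float)
        times = rng.exponential(1.0 / (0.1 * np.exp(1.2 * risk)))
        events = (rng.uniform(size=60) < 0.8).astype(int)
        return scores, np.maximum(times, 1e-3), events

    def test_perfect_separation_worked_example(self):
        scores = pd.Series([0, 0, 0, 10, 10, 10.0])
        times = np.array([10, 11, 12, 1, 2, 3.0])
        events = np.ones(6, dtype=int)
        cut, groups = dichotomize_by_cutpoint(scores, times, events, minprop=0.1)
        assert 0 < cut < 10
        assert (groups == ["low"] * 3 + ["high"] * 3).all()

    def test_matches_exhaustive_scan_oracle(self):
        """Chosen cutpoint equals the argmax of an independent lifelines scan."""
        from lifelines.statistics import logrank_test as ll_logrank

        scores, times, events = self._toy()
        minprop = 0.15
        cut, _ = dichotomize_by_cutpoint(scores, times, events, minprop=minprop)
        uniq = np.unique(scores)
        best_stat, best_cut = -np.inf, None
        n = len(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            low = scores.to_numpy() < c
            if min(low.sum(), n - low.sum()) < minprop * n:
                continue
            stat = ll_logrank(times[low], times[~low],
                              events[low], events[~low]).test_statistic
            if stat > best_stat + 1e-12:
                best_stat, best_cut = stat, c
        assert cut == pytest.approx(best_cut)

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_by_cutpoint(pd.Series(np.ones(20)), np.arange(1.0, 21),
                                    np.ones(20, dtype=int))

    def test_minprop_guard(self):
        scores = pd.Series([0.0] * 19 + [5.0])
        with pytest.raises(ValueError, match="minprop"):
            dichotomize_by_cutpoint(scores, np.arange(1.0, 21),
                                    np.ones(20, dtype=int), minprop=0.2)
        with pytest.raises(ValueError, match="minprop"):
            dichotomize_by_cutpoint(scores, np.arange(1.0, 21),
                                    np.ones(20, dtype=int), minprop=0.7)
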