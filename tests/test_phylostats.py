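import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from shiftorder import phylostats, trees
from shiftorder.phylostats import (collinearity_guard, occurrence_resampling,
                                   phylo_anova, phylo_cov, phylo_lm_fit,
                                   phylo_logistic_fit, phylo_two_sample,
                                   stepwise_reduce)

from conftest import random_yule


def star_cov(n):
    return np.eye(n)


def bm_sample(C, rng, sigma=1.0):
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    return sigma * (L @ rng.standard_normal(len(C)))


class TestCovariance:
    def test_hand_computed_three_tip(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        C = phylo_cov(t, scale=True)
        idx = t.tip_index()
        assert C[idx["A"], idx["B"]] == pytest.approx(0.5)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(C), 1.0)

    def test_psd_on_random_tree(self):
        C = phylo_cov(random_yule(40, 3))
        w = np.linalg.eigvalsh(C)
        assert w.min() > -1e-10


class TestLogistic:
    def test_star_tree_matches_ordinary_logistic(self):
        rng = np.random.default_rng(0)
        n = 150
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 + 1.2 * x)).astype(float)
        fit = phylo_logistic_fit(star_cov(n), y, pd.DataFrame({"x": x}))
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.params.to_numpy() - ref.params)) < 0.05

    def test_fixed_zero_variance_is_exactly_logistic(self):
        rng = np.random.default_rng(1)
        n = 80
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.2 + x)).astype(float)
        fit = phylo_logistic_fit(star_cov(n), y, pd.DataFrame({"x": x}), s2=0.0)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.params.to_numpy() - ref.params)) < 1e-6
        assert fit.pvalues["x"] == pytest.approx(
            2 * stats.norm.sf(abs(ref.tvalues[1])), abs=1e-6)

    def test_perfect_separation_reported(self):
        n = 40
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            phylo_logistic_fit(star_cov(n), y, pd.DataFrame({"x": x}))

    def test_parameter_recovery_on_tree(self):
        # median slope over replicates near the generating value
        tree = random_yule(200, 5, birth=0.25)
        C = phylo_cov(tree)
        rng = np.random.default_rng(7)
        betas = []
        for _ in range(15):
            x = rng.normal(size=200)
            b = bm_sample(C, rng, 0.7)
            y = (rng.random(200) < expit(-0.5 + 2.0 * x + b)).astype(float)
            fit = phylo_logistic_fit(C, y, pd.DataFrame({"elev": x}))
            betas.append(fit.params["elev"])
        assert 1.0 <= np.median(betas) <= 3.0


class TestLinear:
    def test_star_tree_is_ols(self):
        rng = np.random.default_rng(2)
        n = 60
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 1.0 + 0.5 * X["a"] - 0.3 * X["b"] + rng.normal(size=n)
        fit = phylo_lm_fit(star_cov(n), y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.max(np.abs(fit.params.to_numpy() - ref.params.to_numpy())) < 1e-8
        assert np.max(np.abs(fit.pvalues.to_numpy() - ref.pvalues.to_numpy())) < 1e-8

    def test_constant_response(self):
        n = 30
        X = pd.DataFrame({"a": np.linspace(0, 1, n)})
        fit = phylo_lm_fit(star_cov(n), np.full(n, 4.2), X)
        assert fit.params["a"] == pytest.approx(0.0, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(4.2, abs=1e-10)

    def test_scale_equivariance(self):
        tree = random_yule(50, 9)
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        y = bm_sample(phylo_cov(tree), rng) + X["a"].to_numpy()
        f1 = phylo_lm_fit(tree, y, X)
        f2 = phylo_lm_fit(tree, 3.5 * y, X)
        assert np.allclose(f2.params.to_numpy(), 3.5 * f1.params.to_numpy(),
                           atol=1e-10)

    def test_slope_recovery_under_bm(self):
        tree = random_yule(200, 13, birth=0.25)
        C = phylo_cov(tree)
        rng = np.random.default_rng(4)
        slopes = []
        for _ in range(15):
            x = rng.normal(size=200)
            y = 1.5 * x + bm_sample(C, rng, 1.0)
            slopes.append(phylo_lm_fit(C, y, pd.DataFrame({"e": x})).params["e"])
        assert 1.2 <= np.median(slopes) <= 1.8

    def test_singular_design_names_columns(self):
        n = 30
        X = pd.DataFrame({"a": np.arange(n, dtype=float)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            phylo_lm_fit(star_cov(n), np.random.default_rng(0).normal(size=n), X)


class TestTwoSample:
    def test_star_tree_matches_t_test(self):
        rng = np.random.default_rng(5)
        n = 60
        g = np.repeat([0, 1], n // 2)
        y = rng.normal(size=n) + 0.8 * g
        diff, p = phylo_two_sample(star_cov(n), y, g)
        t, p_ref = stats.ttest_ind(y[g == 1], y[g == 0])
        assert diff == pytest.approx(y[g == 1].mean() - y[g == 0].mean(),
                                     abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_label_swap_negates_difference(self):
        rng = np.random.default_rng(6)
        tree = random_yule(40, 21)
        g = rng.integers(0, 2, 40)
        g[:2] = [0, 1]
        y = bm_sample(phylo_cov(tree), rng) + g
        d1, p1 = phylo_two_sample(tree, y, g)
        d2, p2 = phylo_two_sample(tree, y, 1 - g)
        assert d2 == pytest.approx(-d1, abs=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            phylo_two_sample(star_cov(4), np.arange(4.0), np.zeros(4))


class TestAnova:
    def test_star_tree_near_classic_anova(self):
        rng = np.random.default_rng(8)
        n = 90
        g = np.repeat([0, 1, 2], n // 3)
        y = rng.normal(size=n) + 0.6 * (g == 2)
        f, p = phylo_anova(star_cov(n), y, g, nsim=2000, seed=0)
        groups = [y[g == i] for i in range(3)]
        f_ref, p_ref = stats.f_oneway(*groups)
        assert f == pytest.approx(f_ref, abs=1e-9)
        assert abs(p - p_ref) < 0.03

    def test_deterministic_under_seed(self):
        tree = random_yule(50, 31)
        rng = np.random.default_rng(9)
        y = bm_sample(phylo_cov(tree), rng)
        g = rng.integers(0, 2, 50)
        r1 = phylo_anova(tree, y, g, nsim=500, seed=42)
        r2 = phylo_anova(tree, y, g, nsim=500, seed=42)
        assert r1 == r2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            phylo_anova(star_cov(10), np.arange(10.0), np.zeros(10), nsim=100)


class TestStepwise:
    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(10)
        n = 120
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 2.0 * X["a"] - 2.0 * X["b"] + rng.normal(size=n) * 0.5
        fit, log = stepwise_reduce(star_cov(n), y, X, model="linear")
        assert log == []
        assert set(fit.params.index) == {"intercept", "a", "b"}

    def test_hierarchy_interaction_protects_main_effects(self):
        rng = np.random.default_rng(11)
        n = 150
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "a:b": a * b})
        y = 1.5 * a * b + rng.normal(size=n) * 0.5  # pure interaction signal
        fit, log = stepwise_reduce(star_cov(n), y, X, model="linear")
        kept = set(fit.params.index)
        if "a:b" in kept:
            assert {"a", "b"} <= kept

    def test_noise_term_eliminated(self):
        rng = np.random.default_rng(12)
        hits = 0
        n = 100
        for _ in range(20):
            X = pd.DataFrame({"signal": rng.normal(size=n),
                              "noise": rng.normal(size=n)})
            y = 2.0 * X["signal"] + rng.normal(size=n)
            fit, log = stepwise_reduce(star_cov(n), y, X, model="linear")
            if "noise" not in fit.params.index:
                hits += 1
        assert hits >= 16  # >= 80% elimination


class TestResampling:
    def _setup(self, beta, seed, n_species=60, n_rec=5):
        rng = np.random.default_rng(seed)
        tree = random_yule(n_species, seed, birth=0.25)
        C = phylo_cov(tree)
        elev = rng.uniform(0, 2000, n_species)
        b = bm_sample(C, rng, 0.5)
        y = (rng.random(n_species)
             < expit(-1.0 + beta * (elev - 1000) / 500 + b)).astype(float)
        recs = pd.DataFrame({
            "species": np.repeat(tree.tip_labels, n_rec),
            "elevation_m": np.repeat(elev, n_rec)
            + rng.normal(0, 100, n_species * n_rec),
        })
        return tree, recs, pd.Series(y, index=tree.tip_labels)

    def test_deterministic_under_seed(self):
        tree, recs, y = self._setup(3.0, 1)
        r1 = occurrence_resampling(tree, recs, y, n_iter=5, seed=7)
        r2 = occurrence_resampling(tree, recs, y, n_iter=5, seed=7)
        assert r1["pct_significant"] == r2["pct_significant"]

    def test_missing_species_rejected(self):
        tree, recs, y = self._setup(1.0, 2)
        with pytest.raises(ValueError, match="without occurrence"):
            occurrence_resampling(tree, recs[recs["species"] !=
                                            tree.tip_labels[0]], y, n_iter=2)


def test_collinearity_guard():
    rng = np.random.default_rng(13)
    e = rng.uniform(0, 2000, 50)
    X = pd.DataFrame({"elevation": e, "temperature": 27 - 5.5 * e / 1000
                      + rng.normal(0, 0.3, 50)})
    with pytest.raises(ValueError, match="collinear"):
        collinearity_guard(X)
    collinearity_guard(X[["elevation"]])
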