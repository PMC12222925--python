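import numpy as np
import pytest

from shiftorder import markov, trees
from shiftorder.markov import (RateScheme, SSEParams, bm_asr_continuous,
                               correlation_test, fit_mk,
                               fit_models_and_select, marginal_asr, mk_loglik,
                               product_q, sse_loglik)
from shiftorder.studies import _simulate_mk

from conftest import brute_force_loglik, brute_force_marginals, random_yule


def random_instance(rng, max_tips=6, max_states=3):
    n = int(rng.integers(3, max_tips + 1))
    k = int(rng.integers(2, max_states + 1))
    tree = random_yule(n, int(rng.integers(1 << 30)))
    sc = RateScheme(k=k, name="ARD")
    Q = sc.build_q(rng.uniform(0.05, 2.0, sc.n_free))
    ts = rng.integers(0, k, n)
    if len(np.unique(ts)) < 2:
        ts[0] = (ts[0] + 1) % k
    return tree, ts, Q


class TestMkLoglik:
    def test_zero_rates_two_tips(self, cherry):
        Q = np.zeros((2, 2))
        ll = mk_loglik(cherry, np.array([0, 0]), Q, "uniform")
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_two_state_cherry_closed_form(self, cherry):
        # symmetric 2-state: P(same, t) = 1/2 + 1/2 exp(-2qt)
        q = 0.3
        Q = np.array([[-q, q], [q, -q]])
        t = 1.0
        p_same = 0.5 + 0.5 * np.exp(-2 * q * t)
        p_diff = 0.5 - 0.5 * np.exp(-2 * q * t)
        # both tips state 0: sum over root states, uniform prior
        expected = 0.5 * (p_same ** 2 + p_diff ** 2) * 2
        ll = mk_loglik(cherry, np.array([0, 0]), Q, "uniform")
        assert ll == pytest.approx(np.log(0.5 * expected), abs=1e-10)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree, ts, Q = random_instance(rng)
            prior = np.full(Q.shape[0], 1.0 / Q.shape[0])
            assert mk_loglik(tree, ts, Q, prior) == pytest.approx(
                brute_force_loglik(tree, ts, Q, prior), abs=1e-8)

    def test_invariant_to_state_relabeling(self):
        rng = np.random.default_rng(5)
        tree, ts, Q = random_instance(rng, max_states=3)
        k = Q.shape[0]
        perm = rng.permutation(k)
        Qp = Q[np.ix_(perm, perm)]
        inv = np.argsort(perm)
        ll1 = mk_loglik(tree, ts, Q, "uniform")
        ll2 = mk_loglik(tree, inv[ts], Qp, "uniform")
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_missing_state_is_uniform_partial(self, balanced4):
        q = 0.2
        Q = np.array([[-q, q], [q, -q]])
        ll_missing = mk_loglik(balanced4, np.array([0, 1, -1, 0]), Q, "uniform")
        # marginalizing the missing tip by hand
        like = sum(np.exp(mk_loglik(balanced4, np.array([0, 1, s, 0]), Q,
                                    "uniform")) for s in (0, 1))
        assert ll_missing == pytest.approx(np.log(like), abs=1e-10)


class TestMarginalASR:
    def test_matches_enumeration_property(self):
        # 100 random instances, <= 6 tips, <= 3 states, random ARD matrices
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            tree, ts, Q = random_instance(rng)
            prior = np.full(Q.shape[0], 1.0 / Q.shape[0])
            post = marginal_asr(tree, ts, Q, prior)
            exact = brute_force_marginals(tree, ts, Q, prior)
            worst = max(worst, np.max(np.abs(post[tree.n_tips:]
                                             - exact[tree.n_tips:])))
        assert worst <= 1e-8

    def test_vanishing_rates_limit(self, balanced4):
        q = 1e-9
        Q = np.array([[-q, q], [q, -q]])
        post = marginal_asr(balanced4, np.zeros(4, dtype=int), Q, "uniform")
        assert np.all(post[:, 0] > 1 - 1e-6)

    def test_rows_normalized_and_tips_degenerate(self):
        rng = np.random.default_rng(3)
        tree, ts, Q = random_instance(rng)
        post = marginal_asr(tree, ts, Q)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        for i, s in enumerate(ts):
            assert post[i, s] == 1.0


class TestFitMk:
    def test_rate_recovery(self):
        tree = random_yule(200, 123, birth=0.25)
        sc = RateScheme(k=2, name="SYM")
        states = _simulate_mk(tree, sc.build_q([0.1]), 99)
        fit = fit_mk(tree, states, sc, n_restarts=2, seed=0)
        assert 0.05 <= fit.rates[0] <= 0.2

    def test_single_observed_state_warns_and_bounds(self, balanced4):
        sc = RateScheme(k=2, name="SYM")
        with pytest.warns(UserWarning, match="one observed state"):
            fit = fit_mk(balanced4, np.zeros(4, dtype=int), sc, n_restarts=1)
        assert fit.rates[0] <= 1e-5  # at (or within optimizer slack of) the bound

    def test_aic_identity_and_nested_consistency(self):
        tree = random_yule(40, 9)
        sc_sym = RateScheme(k=3, name="SYM")
        states = _simulate_mk(tree, sc_sym.build_q([0.3, 0.2, 0.4]), 17)
        best, table = fit_models_and_select(
            tree, states, [sc_sym, RateScheme(k=3, name="ARD")],
            n_restarts=2, seed=1)
        by = table.set_index("scheme")
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(
                2 * row["n_free"] - 2 * row["loglik"], abs=1e-9)
        assert by.loc["ARD", "loglik"] >= by.loc["SYM", "loglik"] - 1e-6
        assert list(table["aic"]) == sorted(table["aic"])

    def test_single_scheme_trivially_best(self, yule20):
        sc = RateScheme(k=2, name="SYM")
        states = _simulate_mk(yule20, sc.build_q([0.5]), 3)
        best, table = fit_models_and_select(yule20, states, [sc], n_restarts=1)
        assert best.scheme.name == "SYM" and len(table) == 1


class TestSSE:
    def test_reduces_to_mk_when_no_diversification(self):
        rng = np.random.default_rng(21)
        for seed in range(5):
            tree = random_yule(8, seed + 50)
            k = int(rng.integers(2, 4))
            sc = RateScheme(k=k, name="ARD")
            Q = sc.build_q(rng.uniform(0.05, 1.0, sc.n_free))
            ts = rng.integers(0, k, tree.n_tips)
            params = SSEParams(lam=np.zeros(k), mu=np.zeros(k), q=Q)
            assert sse_loglik(tree, ts, params) == pytest.approx(
                mk_loglik(tree, ts, Q), abs=1e-6)

    def test_single_state_equals_birth_death_closed_form(self):
        rng = np.random.default_rng(33)
        for seed in range(3):
            tree = random_yule(8, seed + 80)
            lam = float(rng.uniform(0.5, 1.5))
            mu = float(rng.uniform(0.0, 0.4))
            params = SSEParams(lam=[lam], mu=[mu], q=np.zeros((1, 1)))
            ll = sse_loglik(tree, np.zeros(tree.n_tips, dtype=int), params)
            assert ll == pytest.approx(_bd_closed_form(tree, lam, mu), abs=1e-6)

    def test_full_sampling_boundary_condition(self):
        p = SSEParams(lam=[0.1, 0.2], mu=[0.0, 0.1],
                      q=np.array([[-0.1, 0.1], [0.2, -0.2]]), rho=1.0)
        assert p.rho == 1.0  # E_i(0) = 1 - rho = 0 by construction


def _bd_closed_form(tree, lam, mu):
    """Constant-rate birth-death log-likelihood from the known closed-form
    solutions of the clade (D) and extinction (E) equations with rho = 1."""
    r = lam - mu

    def g(t):
        return np.exp(r * t) / (lam * np.exp(r * t) - mu) ** 2

    ages = tree.ages()
    ll = 0.0
    for v in range(tree.n_nodes - 1):
        ll += np.log(g(ages[tree.parent[v]]) / g(ages[v]))
    for v in range(tree.n_tips, tree.n_nodes):
        ll += (len(tree.children[v]) - 1) * np.log(lam)
    return ll


class TestCorrelationTest:
    def test_independent_loglik_is_sum(self, yule20):
        rng = np.random.default_rng(2)
        sa = rng.integers(0, 2, yule20.n_tips)
        sb = rng.integers(0, 2, yule20.n_tips)
        sa[0] = 1 - sa[1]
        sb[0] = 1 - sb[1]
        res = correlation_test(yule20, sa, sb, n_restarts=1, seed=0)
        assert res["loglik_indep"] == pytest.approx(
            res["fit_a"].loglik + res["fit_b"].loglik, abs=1e-12)
        assert res["n_free_dep"] == 8

    def test_product_matrix_gives_additive_loglik(self, yule20):
        # a dependent-model Q that ignores the partner character must yield
        # exactly the sum of the two single-character log-likelihoods
        rng = np.random.default_rng(8)
        qa = RateScheme(k=2, name="ARD").build_q(rng.uniform(0.1, 1.0, 2))
        qb = RateScheme(k=2, name="ARD").build_q(rng.uniform(0.1, 1.0, 2))
        sa = rng.integers(0, 2, yule20.n_tips)
        sb = rng.integers(0, 2, yule20.n_tips)
        prod_states = sa * 2 + sb
        prior = np.full(4, 0.25)
        ll_prod = mk_loglik(yule20, prod_states, product_q(qa, qb), prior)
        ll_sum = (mk_loglik(yule20, sa, qa, np.full(2, 0.5))
                  + mk_loglik(yule20, sb, qb, np.full(2, 0.5)))
        assert ll_prod == pytest.approx(ll_sum, abs=1e-6)

    def test_large_product_space_refused(self, yule20):
        sa = np.arange(yule20.n_tips) % 5
        sb = np.arange(yule20.n_tips) % 4
        with pytest.raises(ValueError, match="binarize"):
            correlation_test(yule20, sa, sb)


class TestBrownianASR:
    def test_constant_trait_everywhere(self, balanced4):
        vals = bm_asr_continuous(balanced4, np.full(4, 3.7))
        assert np.allclose(vals, 3.7, atol=1e-10)

    def test_cherry_weighted_average(self):
        t = trees.parse_newick("(A:2,B:0.5);")
        v1, v2, t1, t2 = 1.0, 5.0, 2.0, 0.5
        vals = bm_asr_continuous(t, np.array([v1, v2]))
        expected = (v1 / t1 + v2 / t2) / (1 / t1 + 1 / t2)
        assert vals[t.root] == pytest.approx(expected, abs=1e-10)

    def test_star_tree_reduces_to_mean(self):
        t = trees.parse_newick("(A:1,B:1,C:1,D:1);")
        y = np.array([1.0, 2.0, 3.0, 6.0])
        vals = bm_asr_continuous(t, y)
        assert vals[t.root] == pytest.approx(y.mean(), abs=1e-10)

    def test_too_few_tips_rejected(self, cherry):
        with pytest.raises(ValueError):
            bm_asr_continuous(cherry, np.array([1.0]))


def test_constrained_scheme_from_shipped_mask():
    from importlib import resources
    with resources.files("shiftorder.data").joinpath(
            "example_constraint_mask.csv").open() as fh:
        sc = markov.read_zero_mask(fh, k=4)
    assert sc.name == "CONSTRAINED"
    assert sc.n_free == 4 * 3 - 4
    Q = sc.build_q(np.full(sc.n_free, 0.3))
    assert Q[1, 2] == Q[2, 1] == Q[1, 3] == Q[3, 1] == 0.0
    assert Q[0, 1] == 0.3
    assert np.allclose(Q.sum(axis=1), 0.0)
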