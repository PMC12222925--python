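"""Continuous-time Markov (Mk) and state-dependent diversification likelihoods.

Implements, on the array-backed :class:`~shiftorder.trees.Phylogeny`:

* Felsenstein-pruning log-likelihood for k-state Mk models with SYM / ARD /
  constrained rate schemes and uniform / stationary / FitzJohn root priors;
* marginal ancestral state probabilities by the standard inside-outside
  (rerooting-equivalent) pass;
* a MuSSE-style state-dependent speciation-extinction (SSE) likelihood by
  per-branch integration of the D/E ODE system;
* maximum-likelihood fitting with log-parameterized rates, bounded multi-start
  optimization, and AIC-based model selection;
* the dependent-vs-independent correlated-evolution test on the product state
  space of two characters;
* Brownian-motion ancestral reconstruction of a continuous character.

Transition matrices P(t) = exp(Qt) are computed by eigendecomposition of Q
(one decomposition per likelihood evaluation, vectorized over branches) with a
scaling-and-squaring ``expm`` fallback when Q is defective or ill-conditioned;
state spaces here are tiny (k <= 16).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.integrate import solve_ivp

from .trees import Phylogeny

ROOT_PRIORS = ("uniform", "stationary", "fitzjohn")
RATE_BOUNDS = (1e-9, 100.0)  # per Myr


# ---------------------------------------------------------------------------
# rate schemes and matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateScheme:
    """Parameterization of the off-diagonal cells of a k-state rate matrix.

    ``SYM`` shares one rate per unordered state pair (k(k-1)/2 free rates),
    ``ARD`` gives every ordered pair its own rate (k(k-1)), and
    ``CONSTRAINED`` is ARD with the cells in ``mask`` fixed at zero.
    """

    k: int
    name: str  # SYM | ARD | CONSTRAINED
    mask: frozenset = frozenset()  # forbidden (i, j) off-diagonal cells

    def __post_init__(self):
        if self.name not in ("SYM", "ARD", "CONSTRAINED"):
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.name != "CONSTRAINED" and self.mask:
            raise ValueError("only CONSTRAINED schemes take a zero mask")
        for (i, j) in self.mask:
            if i == j or not (0 <= i < self.k and 0 <= j < self.k):
                raise ValueError(f"invalid mask cell {(i, j)}")

    def param_map(self) -> dict[tuple[int, int], int]:
        """Map each free off-diagonal cell to its parameter index."""
        out: dict[tuple[int, int], int] = {}
        if self.name == "SYM":
            p = 0
            for i in range(self.k):
                for j in range(i + 1, self.k):
                    out[(i, j)] = p
                    out[(j, i)] = p
                    p += 1
        else:
            p = 0
            for i in range(self.k):
                for j in range(self.k):
                    if i != j and (i, j) not in self.mask:
                        out[(i, j)] = p
                        p += 1
        return out

    @property
    def n_free(self) -> int:
        return len(set(self.param_map().values()))

    def build_q(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} rates, got {rates.shape}")
        Q = np.zeros((self.k, self.k))
        for (i, j), p in self.param_map().items():
            Q[i, j] = rates[p]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def read_zero_mask(path, k: int) -> RateScheme:
    """Build a CONSTRAINED scheme from a CSV of forbidden transitions.

    The file has columns ``from_state,to_state`` (0-based state codes); an
    example forbidding direct transitions among the shifted pollination
    syndromes ships with the package as
    ``data/example_constraint_mask.csv``.
    """
    df = pd.read_csv(path, comment="#")
    cells = frozenset((int(r["from_state"]), int(r["to_state"]))
                      for _, r in df.iterrows())
    return RateScheme(k=k, name="CONSTRAINED", mask=cells)


def validate_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k):
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(Q))):
        raise ValueError("rows of Q must sum to 0")
    return Q


def transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """P(t_b) = exp(Q t_b) for every branch length in ``t``, shape (B, k, k)."""
    t = np.asarray(t, dtype=float)
    k = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e8:
            ew = np.exp(np.outer(t, w))  # (B, k)
            P = np.einsum("ij,bj,jk->bik", U, ew, Uinv)
            P = P.real
            err = np.max(np.abs(P.sum(axis=2) - 1.0))
            if err < 1e-8:
                return np.clip(P, 0.0, None)
    except np.linalg.LinAlgError:
        pass
    # fallback: dense expm per branch (defective or ill-conditioned Q)
    P = np.empty((len(t), k, k))
    for b, tb in enumerate(t):
        P[b] = linalg.expm(Q * tb)
    return np.clip(P, 0.0, None)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _tip_partials(tree: Phylogeny, tip_states: np.ndarray, k: int) -> np.ndarray:
    """One-hot partial likelihoods; missing states (-1) get a uniform row."""
    tip_states = np.asarray(tip_states, dtype=int)
    if tip_states.shape != (tree.n_tips,):
        raise ValueError("tip_states must have one entry per tip")
    if np.any(tip_states >= k):
        raise ValueError("tip state out of range")
    D = np.zeros((tree.n_tips, k))
    obs = tip_states >= 0
    D[np.flatnonzero(obs), tip_states[obs]] = 1.0
    D[~obs] = 1.0
    return D


def _root_prior_vector(prior, Q, d_root, k):
    if isinstance(prior, np.ndarray):
        p = prior / prior.sum()
    elif prior == "uniform":
        p = np.full(k, 1.0 / k)
    elif prior == "stationary":
        p = stationary_distribution(Q)
    elif prior == "fitzjohn":
        s = d_root.sum()
        p = d_root / s if s > 0 else np.full(k, 1.0 / k)
    else:
        raise ValueError(f"unknown root prior {prior!r}")
    return p


def _pruning_pass(tree: Phylogeny, tip_states, Q):
    """Postorder partials.

    Returns (D, M, logscale) where D[v] is the scaled conditional likelihood
    of the subtree below v given the state at v, M[v] = P_v @ D[v] is the
    message through the branch above v, and logscale is the accumulated log
    of the per-node normalization constants.
    """
    k = Q.shape[0]
    P = transition_matrices(Q, tree.blen)
    D = np.zeros((tree.n_nodes, k))
    D[: tree.n_tips] = _tip_partials(tree, tip_states, k)
    M = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    for v in range(tree.n_tips):
        M[v] = P[v] @ D[v]
    for v in range(tree.n_tips, tree.n_nodes):
        d = np.ones(k)
        for c in tree.children[v]:
            d *= M[c]
        s = d.sum()
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError(
                f"non-finite partial likelihood at node {v} "
                f"(children {tree.children[v]}); check Q and branch lengths"
            )
        D[v] = d / s
        logscale += np.log(s)
        if v != tree.root:
            M[v] = P[v] @ D[v]
    return D, M, P, logscale


def mk_loglik(tree: Phylogeny, tip_states, Q, root_prior="fitzjohn") -> float:
    """Mk log-likelihood by Felsenstein pruning.

    ``tip_states`` is an int array over tips (state codes ``0..k-1``, ``-1``
    for missing).  The FitzJohn prior weights root states by their relative
    contribution to the likelihood.
    """
    Q = validate_q(Q)
    D, _, _, logscale = _pruning_pass(tree, tip_states, Q)
    d_root = D[tree.root]
    p = _root_prior_vector(root_prior, Q, d_root, Q.shape[0])
    like = float(p @ d_root)
    if like <= 0:
        return -np.inf
    return float(np.log(like) + logscale)


def marginal_asr(tree: Phylogeny, tip_states, Q, root_prior="fitzjohn") -> np.ndarray:
    """Marginal state probabilities at every node, shape (n_nodes, k).

    Inside-outside pass: the outside vector F of a child c of v combines the
    outside vector of v with the messages of c's siblings, transported through
    c's branch; the marginal at c is then proportional to ``D[c] * F[c]``.
    Observed tips are returned as degenerate (one-hot) rows.
    """
    Q = validate_q(Q)
    k = Q.shape[0]
    D, M, P, _ = _pruning_pass(tree, tip_states, Q)
    prior = _root_prior_vector(root_prior, Q, D[tree.root], k)
    F = np.zeros((tree.n_nodes, k))
    F[tree.root] = prior
    for v in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        kids = tree.children[v]
        msgs = np.array([M[c] for c in kids])
        for pos, c in enumerate(kids):
            sib = np.prod(np.delete(msgs, pos, axis=0), axis=0) if len(kids) > 1 else np.ones(k)
            s = F[v] * sib
            f = P[c].T @ s
            tot = f.sum()
            F[c] = f / tot if tot > 0 else np.full(k, 1.0 / k)
    post = D * F
    norm = post.sum(axis=1, keepdims=True)
    bad = norm[:, 0] <= 0
    post[bad] = 1.0 / k
    norm[bad] = 1.0
    post = post / norm
    # observed tips are known states
    ts = np.asarray(tip_states, dtype=int)
    obs = np.flatnonzero(ts >= 0)
    post[obs] = 0.0
    post[obs, ts[obs]] = 1.0
    return post


# ---------------------------------------------------------------------------
# ML fitting and model selection
# ---------------------------------------------------------------------------

@dataclass
class RateModelFit:
    scheme: RateScheme
    rates: np.ndarray
    q: np.ndarray
    loglik: float
    converged: bool
    root_prior: str = "fitzjohn"
    trace: list = field(default_factory=list)
    engine: str = "mk"
    sse_params: "SSEParams | None" = None

    @property
    def n_free(self) -> int:
        n = self.scheme.n_free
        if self.engine == "sse":
            n += 2 * self.scheme.k  # per-state lambda and mu
        return n

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme.name,
            "k": self.scheme.k,
            "engine": self.engine,
            "rates": np.asarray(self.rates).tolist(),
            "loglik": self.loglik,
            "n_free": self.n_free,
            "aic": self.aic,
            "converged": self.converged,
            "root_prior": self.root_prior,
        }
        if self.sse_params is not None:
            d["lambda"] = self.sse_params.lam.tolist()
            d["mu"] = self.sse_params.mu.tolist()
            d["rho"] = self.sse_params.rho
        return d


def _multi_start_minimize(neg_loglik, n_par, tree_height, n_restarts, seed,
                          extra_starts=()):
    rng = np.random.default_rng(seed)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    base = np.log(max(1.0 / max(tree_height, 1e-6), RATE_BOUNDS[0] * 10))
    starts = [np.full(n_par, base)]
    for x in extra_starts:
        starts.append(np.clip(np.asarray(x, dtype=float), lo, hi))
    while len(starts) < n_restarts + len(extra_starts):
        starts.append(np.clip(base + rng.uniform(-2.0, 2.0, size=n_par), lo, hi))
    best = None
    trace = []
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B",
            bounds=[(lo, hi)] * n_par,
        )
        trace.append({"x0": x0.tolist(), "loglik": -res.fun, "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    return best, trace


def fit_mk(tree: Phylogeny, tip_states, scheme: RateScheme,
           root_prior="fitzjohn", n_restarts=5, seed=0,
           extra_starts=()) -> RateModelFit:
    """ML Mk fit with bounded multi-start optimization on log rates.

    ``extra_starts`` takes log-rate vectors (e.g. a nested model's solution
    expanded to this scheme's parameterization) used as additional starting
    points; model selection uses this to keep nested log-likelihoods ordered.
    """
    ts = np.asarray(tip_states, dtype=int)
    observed_states = np.unique(ts[ts >= 0])
    if observed_states.size < 2:
        warnings.warn("only one observed state; rates are not identifiable "
                      "and will run to the lower bound", stacklevel=2)

    def neg(x):
        Q = scheme.build_q(np.exp(x))
        try:
            ll = mk_loglik(tree, ts, Q, root_prior)
        except FloatingPointError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    best, trace = _multi_start_minimize(
        neg, scheme.n_free, tree.height(), n_restarts, seed, extra_starts)
    rates = np.exp(best.x)
    return RateModelFit(
        scheme=scheme, rates=rates, q=scheme.build_q(rates),
        loglik=-best.fun, converged=bool(best.success),
        root_prior=root_prior if isinstance(root_prior, str) else "custom",
        trace=trace,
    )


def _expand_rates(from_scheme: RateScheme, rates, to_scheme: RateScheme):
    """Express a nested model's Q in a richer scheme's log-rate vector."""
    Q = from_scheme.build_q(rates)
    out = np.full(to_scheme.n_free, np.log(RATE_BOUNDS[0]))
    for (i, j), p in to_scheme.param_map().items():
        if Q[i, j] > 0:
            out[p] = np.log(Q[i, j])
    return out


def fit_models_and_select(tree, tip_states, schemes, engine="mk",
                          root_prior="fitzjohn", n_restarts=5, seed=0,
                          rho=1.0):
    """Fit each scheme, rank by AIC (ties toward fewer parameters).

    Returns (best_fit, table) where the table is a DataFrame sorted by AIC
    ascending.  Schemes are fitted in order of increasing parameter count and
    each fit seeds the next with the previous solution so nested models keep
    logL monotone.
    """
    if not schemes:
        raise ValueError("need at least one scheme")
    schemes = sorted(schemes, key=lambda s: s.n_free)
    fits: list[RateModelFit] = []
    prev: RateModelFit | None = None
    for sc in schemes:
        extra = []
        if prev is not None and prev.scheme.n_free <= sc.n_free:
            extra.append(_expand_rates(prev.scheme, prev.rates, sc))
        if engine == "mk":
            fit = fit_mk(tree, tip_states, sc, root_prior, n_restarts, seed,
                         extra_starts=extra)
        elif engine == "sse":
            fit = fit_sse(tree, tip_states, sc, rho=rho, root_prior=root_prior,
                          n_restarts=max(1, n_restarts // 2), seed=seed)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        fits.append(fit)
        if prev is None or fit.loglik > prev.loglik:
            prev = fit
    if not any(f.converged for f in fits):
        raise RuntimeError("no scheme converged")
    table = pd.DataFrame([f.to_dict() for f in fits])
    table = table.sort_values(["aic", "n_free"], kind="stable").reset_index(drop=True)
    order = {f.scheme.name: f for f in fits}
    best = order[table.loc[0, "scheme"]]
    return best, table


# ---------------------------------------------------------------------------
# state-dependent speciation/extinction (MuSSE-style)
# ---------------------------------------------------------------------------

@dataclass
class SSEParams:
    """Per-state speciation/extinction rates plus a transition matrix.

    ``rho`` is the (state-independent) sampling fraction of extant species.
    """

    lam: np.ndarray
    mu: np.ndarray
    q: np.ndarray
    rho: float = 1.0

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.q = validate_q(self.q)
        k = self.q.shape[0]
        if self.lam.shape != (k,) or self.mu.shape != (k,):
            raise ValueError("lambda and mu must have one entry per state")
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValueError("lambda and mu must be >= 0")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


def sse_loglik(tree: Phylogeny, tip_states, params: SSEParams,
               root_prior="fitzjohn", condition_on_survival=False,
               rtol=1e-8, atol=1e-10) -> float:
    """MuSSE-style log-likelihood by backward ODE integration along branches.

    The standard D/E system is integrated rootward per branch with
    ``E_i(0) = 1 - rho`` and ``D_i(0) = rho * 1[tip state = i]`` at the tips;
    daughters are joined at nodes with a lambda-weighted product.  When all
    speciation rates are zero the process contains no speciation events, node
    joining degenerates to a plain product, and the likelihood reduces
    exactly to the Mk likelihood.
    """
    k = params.q.shape[0]
    lam, mu, Q = params.lam, params.mu, params.q
    row_out = lam + mu - np.diag(Q)  # lambda_i + mu_i + sum_j q_ij
    Qoff = Q - np.diag(np.diag(Q))
    speciation_factors = bool(np.any(lam > 0))

    def rhs(_t, y):
        E, D = y[:k], y[k:]
        dE = mu - row_out * E + Qoff @ E + lam * E * E
        dD = -row_out * D + Qoff @ D + 2.0 * lam * E * D
        return np.concatenate([dE, dD])

    tipD = _tip_partials(tree, tip_states, k) * params.rho
    E0 = np.full(k, 1.0 - params.rho)
    E = np.zeros((tree.n_nodes, k))
    D = np.zeros((tree.n_nodes, k))
    logscale = 0.0

    def up_branch(v, Ev, Dv):
        nonlocal logscale
        t = tree.blen[v]
        if t == 0:
            return Ev, Dv
        sol = solve_ivp(rhs, (0.0, t), np.concatenate([Ev, Dv]),
                        method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on branch above node {v}: "
                               f"{sol.message}")
        y = sol.y[:, -1]
        Eout, Dout = y[:k], np.clip(y[k:], 0.0, None)
        return Eout, Dout

    for v in range(tree.n_tips):
        E[v], D[v] = up_branch(v, E0, tipD[v])
    for v in range(tree.n_tips, tree.n_nodes):
        kids = tree.children[v]
        d = np.ones(k)
        for c in kids:
            d *= D[c]
        if speciation_factors:
            d *= lam ** (len(kids) - 1)
        s = d.sum()
        if not np.isfinite(s) or s <= 0:
            return -np.inf
        logscale += np.log(s)
        d = d / s
        e = E[kids[0]]
        if v == tree.root:
            E[v], D[v] = e, d
        else:
            E[v], D[v] = up_branch(v, e, d)

    prior = _root_prior_vector(root_prior, Q, D[tree.root], k)
    like = float(prior @ D[tree.root])
    if like <= 0:
        return -np.inf
    ll = np.log(like) + logscale
    if condition_on_survival:
        denom = float(prior @ (lam * (1.0 - E[tree.root]) ** 2))
        if denom <= 0:
            return -np.inf
        ll -= np.log(denom)
    return float(ll)


def fit_sse(tree, tip_states, scheme: RateScheme, rho=1.0,
            root_prior="fitzjohn", n_restarts=2, seed=0,
            condition_on_survival=False) -> RateModelFit:
    """ML MuSSE-style fit (per-state lambda, mu plus scheme rates).

    Optimization is over log parameters; this is the slow engine and is meant
    for modest tree sizes — the scenario pipeline uses the Mk engine by
    default.
    """
    k = scheme.k
    nq = scheme.n_free

    def neg(x):
        r = np.exp(x)
        params = SSEParams(lam=r[nq:nq + k], mu=r[nq + k:], q=scheme.build_q(r[:nq]),
                           rho=rho)
        try:
            ll = sse_loglik(tree, tip_states, params, root_prior,
                            condition_on_survival)
        except RuntimeError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    best, trace = _multi_start_minimize(
        neg, nq + 2 * k, tree.height(), n_restarts, seed)
    r = np.exp(best.x)
    params = SSEParams(lam=r[nq:nq + k], mu=r[nq + k:], q=scheme.build_q(r[:nq]),
                       rho=rho)
    return RateModelFit(
        scheme=scheme, rates=r[:nq], q=params.q, loglik=-best.fun,
        converged=bool(best.success), root_prior=root_prior, trace=trace,
        engine="sse", sse_params=params,
    )


# ---------------------------------------------------------------------------
# correlated evolution (dependent vs independent product-space Mk)
# ---------------------------------------------------------------------------

def product_q(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Rate matrix of two independently evolving characters on the product
    state space (a, b) -> a * k_b + b."""
    ka, kb = qa.shape[0], qb.shape[0]
    return np.kron(qa, np.eye(kb)) + np.kron(np.eye(ka), qb)


def dependent_scheme(ka: int, kb: int) -> RateScheme:
    """ARD on the product space with simultaneous double transitions forbidden."""
    mask = set()
    for a1 in range(ka):
        for b1 in range(kb):
            for a2 in range(ka):
                for b2 in range(kb):
                    if (a1, b1) == (a2, b2):
                        continue
                    if a1 != a2 and b1 != b2:
                        mask.add((a1 * kb + b1, a2 * kb + b2))
    return RateScheme(k=ka * kb, name="CONSTRAINED", mask=frozenset(mask))


def correlation_test(tree, states_a, states_b, scheme_name="ARD",
                     root_prior="fitzjohn", n_restarts=3, seed=0) -> dict:
    """Pagel-style test: do two discrete characters evolve dependently?

    The independent model is two separate Mk fits (log-likelihoods and
    parameter counts add); the dependent model is an Mk fit on the product
    state space where each rate may depend on the partner character's state
    but simultaneous change of both characters is forbidden.  The verdict is
    the model with the lower AIC.
    """
    sa = np.asarray(states_a, dtype=int)
    sb = np.asarray(states_b, dtype=int)
    ka = max(2, int(sa[sa >= 0].max()) + 1)
    kb = max(2, int(sb[sb >= 0].max()) + 1)
    if ka * kb > 16:
        raise ValueError(
            f"product state space has {ka * kb} states (> 16); "
            "binarize the characters before testing")

    def mk_scheme(k):
        return RateScheme(k=k, name="SYM") if scheme_name == "SYM" else \
            RateScheme(k=k, name="ARD")

    fit_a = fit_mk(tree, sa, mk_scheme(ka), root_prior, n_restarts, seed)
    fit_b = fit_mk(tree, sb, mk_scheme(kb), root_prior, n_restarts, seed + 1)
    ll_indep = fit_a.loglik + fit_b.loglik
    n_indep = fit_a.n_free + fit_b.n_free
    aic_indep = 2 * n_indep - 2 * ll_indep

    prod_states = np.where((sa >= 0) & (sb >= 0), sa * kb + sb, -1)
    dep = dependent_scheme(ka, kb)
    # seed the dependent fit from the independent solution
    q0 = product_q(fit_a.q, fit_b.q)
    x0 = np.full(dep.n_free, np.log(RATE_BOUNDS[0]))
    for (i, j), p in dep.param_map().items():
        if q0[i, j] > 0:
            x0[p] = np.log(q0[i, j])
    fit_dep = fit_mk(tree, prod_states, dep, root_prior, n_restarts, seed + 2,
                     extra_starts=[x0])
    return {
        "loglik_indep": ll_indep,
        "aic_indep": aic_indep,
        "n_free_indep": n_indep,
        "loglik_dep": fit_dep.loglik,
        "aic_dep": fit_dep.aic,
        "n_free_dep": fit_dep.n_free,
        "verdict": "dependent" if fit_dep.aic < aic_indep else "independent",
        "fit_a": fit_a,
        "fit_b": fit_b,
        "fit_dep": fit_dep,
    }


# ---------------------------------------------------------------------------
# Brownian-motion ancestral reconstruction of a continuous trait
# ---------------------------------------------------------------------------

def bm_asr_continuous(tree: Phylogeny, tip_values) -> np.ndarray:
    """ML ancestral values under Brownian motion, one value per node.

    The joint ML solution minimizes sum_edges (x_parent - x_child)^2 / t_edge
    over the internal values, i.e. a weighted tree-Laplacian linear system;
    on a two-tip cherry the root collapses to the classic inverse-branch-
    length weighted average.
    """
    y = np.asarray(tip_values, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValueError("tip_values must have one entry per tip")
    if tree.n_tips < 2:
        raise ValueError("need at least two tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("tip values must be finite")
    n_int = tree.n_nodes - tree.n_tips
    A = np.zeros((n_int, n_int))
    b = np.zeros(n_int)
    eps = 1e-10 * max(tree.height(), 1.0)
    for v in range(tree.n_nodes - 1):
        p = tree.parent[v]
        w = 1.0 / max(tree.blen[v], eps)
        pi = p - tree.n_tips
        A[pi, pi] += w
        if v < tree.n_tips:
            b[pi] += w * y[v]
        else:
            vi = v - tree.n_tips
            A[vi, vi] += w
            A[pi, vi] -= w
            A[vi, pi] -= w
    x = np.linalg.solve(A, b)
    return np.concatenate([y, x])
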