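"""Phylogenetically corrected regressions and tests.

All methods share the Brownian-motion phylogenetic covariance matrix C
(shared root-to-MRCA path lengths, scaled to unit height):

* :func:`phylo_logistic_fit` — binary phylogenetic GLMM (logistic link,
  random effect b ~ N(0, s2 C)) estimated by the penalized-quasi-likelihood
  scheme of the Ives-Garland formulation;
* :func:`phylo_lm_fit` — phylogenetic linear model, i.e. GLS with residual
  covariance sigma^2 C (delegated to statsmodels GLS);
* :func:`phylo_two_sample` — phylogenetic two-sample (t-style) test via a
  group indicator in the linear model;
* :func:`phylo_anova` — simulation-based phylogenetic ANOVA: the observed
  one-way F statistic is referred to a null distribution of F values from
  Brownian-motion simulations on the tree;
* :func:`stepwise_reduce` — backward elimination keeping the model hierarchy
  (interactions are dropped before their main effects);
* :func:`occurrence_resampling` — the repeated single-occurrence-per-species
  refit, reporting the percentage of iterations with P < 0.05.

On a star phylogeny (C = I) every routine reduces to its classical,
non-phylogenetic counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from scipy.special import expit

from .trees import Phylogeny


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------

def phylo_cov(tree: Phylogeny, scale: bool = True) -> np.ndarray:
    """Brownian-motion covariance among tips: C_ij = depth of MRCA(i, j),
    scaled by tree height so the diagonal is 1 on an ultrametric tree."""
    d = tree.depths()
    tips_below = tree.subtree_tips()
    n = tree.n_tips
    C = np.zeros((n, n))
    for v in range(tree.n_tips, tree.n_nodes):
        kids = tree.children[v]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ta, tb = tips_below[kids[a]], tips_below[kids[b]]
                C[np.ix_(ta, tb)] = d[v]
                C[np.ix_(tb, ta)] = d[v]
    np.fill_diagonal(C, d[:n])
    if scale:
        C = C / tree.height()
    return C


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_singular(X: np.ndarray, names: list[str]) -> None:
    Xd = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        # identify offending columns by near-zero R diagonal
        _, R = np.linalg.qr(Xd)
        diag = np.abs(np.diag(R))
        bad = [names[i - 1] for i in range(1, Xd.shape[1])
               if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def collinearity_guard(X: pd.DataFrame, r_max: float = 0.8) -> None:
    """Refuse designs with strongly correlated predictor pairs (|r| > r_max),
    e.g. elevation together with temperature."""
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            xi, xj = X[cols[i]], X[cols[j]]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            if abs(r) > r_max:
                raise ValueError(
                    f"predictors {cols[i]!r} and {cols[j]!r} are collinear "
                    f"(|r| = {abs(r):.2f} > {r_max}); include only one")


# ---------------------------------------------------------------------------
# binary phylogenetic GLMM (PQL)
# ---------------------------------------------------------------------------

@dataclass
class PhyloGlmFit:
    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    s2: float
    mu: np.ndarray
    converged: bool
    n_iter: int
    log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.se,
                             "z": self.zvalues, "p": self.pvalues})


def _pql_inner(C, Xd, Z, invW, s2):
    """One generalized-least-squares step of the working linear mixed model.

    Returns (criterion, beta, b): the REML-type penalized quasi-likelihood
    criterion, the fixed effects, and the phylogenetic random effects.
    """
    V = np.diag(invW) + s2 * C
    cf = linalg.cho_factor(V, lower=True)
    invV_X = linalg.cho_solve(cf, Xd)
    invV_Z = linalg.cho_solve(cf, Z)
    XtVX = Xd.T @ invV_X
    beta = np.linalg.solve(XtVX, Xd.T @ invV_Z)
    H = Z - Xd @ beta
    invV_H = linalg.cho_solve(cf, H)
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    crit = 0.5 * (logdetV + logdetXtVX + H @ invV_H)
    b = s2 * (C @ invV_H)
    return crit, beta, b, XtVX


def phylo_logistic_fit(tree, y, X, s2=None, max_iter: int = 200,
                       tol: float = 1e-6, standardize: bool = True) -> PhyloGlmFit:
    """Binary phylogenetic GLMM by penalized quasi-likelihood.

    logit P(y_i = 1) = x_i' beta + b_i with b ~ N(0, s2 C); s2 is profiled
    out by a bounded one-dimensional REML-type optimization inside each PQL
    update (pass ``s2`` to fix it instead, 0 giving ordinary logistic
    regression).  Predictors are standardized internally and coefficients
    back-transformed; p-values use the normal (z) reference.
    """
    C = phylo_cov(tree) if isinstance(tree, Phylogeny) else np.asarray(tree, float)
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    Xraw, names = _as_design(X)
    n = len(y)
    if C.shape != (n, n):
        raise ValueError("covariance and response sizes differ")
    try:
        np.linalg.cholesky(C + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError:
        raise ValueError("phylogenetic covariance is not positive semi-definite")
    _check_singular(Xraw, names)

    means = Xraw.mean(axis=0)
    sds = Xraw.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xs = (Xraw - means) / sds if standardize else Xraw
    Xd = np.column_stack([np.ones(n), Xs])
    colnames = ["intercept"] + names

    # initial ordinary logistic fit; also the perfect-separation guard
    glm = sm.GLM(y, Xd, family=sm.families.Binomial())
    try:
        res0 = glm.fit(maxiter=100)
        beta = np.asarray(res0.params)
    except Exception:
        beta = np.zeros(Xd.shape[1])
    mu0 = expit(Xd @ beta)
    if np.all((mu0 > 1 - 1e-8) == (y == 1)) and np.all(np.abs(mu0 - y) < 1e-8):
        worst = names[int(np.argmax(np.abs(beta[1:])))]
        raise ValueError(f"perfect separation (predictor {worst!r})")

    b = np.zeros(n)
    s2_cur = 0.1 if s2 is None else float(s2)
    converged = False
    log = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta + b
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        W = mu * (1 - mu)
        invW = 1.0 / W
        Z = eta + (y - mu) / W
        if s2 is None:
            res = optimize.minimize_scalar(
                lambda ls: _pql_inner(C, Xd, Z, invW, np.exp(ls))[0],
                bounds=(np.log(1e-8), np.log(50.0)), method="bounded",
                options={"xatol": 1e-8})
            s2_new = float(np.exp(res.x))
        else:
            s2_new = float(s2)
        _, beta_new, b_new, XtVX = _pql_inner(C, Xd, Z, invW, s2_new)
        delta = max(np.max(np.abs(beta_new - beta)) / (1 + np.max(np.abs(beta))),
                    abs(s2_new - s2_cur) / (1 + s2_cur))
        log.append({"iter": it, "s2": s2_new, "delta": float(delta)})
        beta, b, s2_cur = beta_new, b_new, s2_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PQL did not converge in {max_iter} iterations",
                      stacklevel=2)
    se = np.sqrt(np.diag(np.linalg.inv(XtVX)))
    if standardize:
        # back-transform from z-scored predictors to the original scale
        beta_o = beta.copy()
        se_o = se.copy()
        beta_o[1:] = beta[1:] / sds
        se_o[1:] = se[1:] / sds
        beta_o[0] = beta[0] - np.sum(beta[1:] * means / sds)
        beta, se = beta_o, se_o
    zv = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pv = 2 * stats.norm.sf(np.abs(zv))
    mu_fit = np.clip(expit(beta[0] + Xraw @ beta[1:] + b), 1e-12, 1 - 1e-12)
    idx = pd.Index(colnames)
    return PhyloGlmFit(
        params=pd.Series(beta, index=idx), se=pd.Series(se, index=idx),
        zvalues=pd.Series(zv, index=idx), pvalues=pd.Series(pv, index=idx),
        s2=s2_cur, mu=mu_fit, converged=converged, n_iter=it, log=log)


# ---------------------------------------------------------------------------
# phylogenetic linear model (GLS)
# ---------------------------------------------------------------------------

@dataclass
class PhyloLmFit:
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    resid: np.ndarray
    df_resid: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.se,
                             "t": self.tvalues, "p": self.pvalues})


def phylo_lm_fit(tree, y, X) -> PhyloLmFit:
    """Phylogenetic linear model: GLS with residual covariance sigma^2 C.

    Any transform of the response (the petal-length and pore-area models use
    logs) is applied by the caller.  On a star tree this is ordinary least
    squares.
    """
    C = phylo_cov(tree) if isinstance(tree, Phylogeny) else np.asarray(tree, float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response must be finite")
    Xraw, names = _as_design(X)
    _check_singular(Xraw, names)
    Xd = np.column_stack([np.ones(len(y)), Xraw])
    res = sm.GLS(y, Xd, sigma=C).fit()
    idx = pd.Index(["intercept"] + names)
    return PhyloLmFit(
        params=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        sigma2=float(res.scale),
        resid=np.asarray(res.resid),
        df_resid=int(res.df_resid),
    )


def phylo_two_sample(tree, y, group) -> tuple[float, float]:
    """Phylogenetic two-sample test: the group-indicator coefficient of a
    phylogenetic linear model, with its p-value."""
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    ind = (g == levels[1]).astype(float)
    if ind.sum() in (0, len(ind)):
        raise ValueError("one group is empty")
    fit = phylo_lm_fit(tree, y, pd.DataFrame({"group": ind}))
    return float(fit.params["group"]), float(fit.pvalues["group"])


# ---------------------------------------------------------------------------
# simulation-based phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _f_stats(Y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """One-way ANOVA F for each column of Y (n x m)."""
    n, m = Y.shape
    grand = Y.mean(axis=0)
    ssb = np.zeros(m)
    ssw = np.zeros(m)
    for g in range(k):
        Yg = Y[codes == g]
        mg = Yg.mean(axis=0)
        ssb += len(Yg) * (mg - grand) ** 2
        ssw += ((Yg - mg) ** 2).sum(axis=0)
    return (ssb / (k - 1)) / (ssw / (n - k))


def phylo_anova(tree, y, group, nsim: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F statistic is compared with F statistics from
    ``nsim`` Brownian-motion simulations on the tree (single BM rate
    estimated by ML from the data); p = (1 + #{F_sim >= F_obs}) / (nsim + 1).
    """
    if nsim < 100:
        raise ValueError("nsim must be >= 100")
    C = phylo_cov(tree) if isinstance(tree, Phylogeny) else np.asarray(tree, float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    levels, codes = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need at least two groups")
    n = len(y)
    f_obs = float(_f_stats(y[:, None], codes, k)[0])
    # ML Brownian rate from the phylogenetic mean
    cf = linalg.cho_factor(C + 1e-12 * np.eye(n), lower=True)
    one = np.ones(n)
    invC_y = linalg.cho_solve(cf, y)
    invC_1 = linalg.cho_solve(cf, one)
    mu = float(one @ invC_y) / float(one @ invC_1)
    r = y - mu
    sigma2 = float(r @ linalg.cho_solve(cf, r)) / n
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    Ysim = mu + np.sqrt(sigma2) * (L @ rng.standard_normal((n, nsim)))
    f_sim = _f_stats(Ysim, codes, k)
    p = (1.0 + np.sum(f_sim >= f_obs)) / (nsim + 1.0)
    return f_obs, float(p)


# ---------------------------------------------------------------------------
# backward stepwise selection
# ---------------------------------------------------------------------------

def _interaction_parts(name: str) -> list[str]:
    return name.split(":") if ":" in name else []


def stepwise_reduce(tree, y, X: pd.DataFrame, model: str = "logistic",
                    alpha: float = 0.05, **fit_kw):
    """Backward elimination of non-significant terms.

    Repeatedly drops the term with the largest p-value above ``alpha`` (ties
    broken toward the larger column index), never removing a main effect
    while an interaction containing it (column named ``"a:b"``) is retained.
    Returns (final fit, elimination log); an intercept-only final model is
    allowed and flagged in the log.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    fitter = {"logistic": phylo_logistic_fit, "linear": phylo_lm_fit}[model]
    cols = list(X.columns)
    log = []
    while True:
        fit = fitter(tree, y, X[cols], **fit_kw) if cols else \
            fitter(tree, y, pd.DataFrame(index=X.index), **fit_kw)
        if not cols:
            log.append({"action": "intercept-only model"})
            break
        pvals = fit.pvalues.drop("intercept")
        protected = set()
        for c in cols:
            for part in _interaction_parts(c):
                protected.add(part)
        candidates = [(c, pvals[c]) for c in cols
                      if pvals[c] > alpha and c not in protected]
        if not candidates:
            break
        worst_p = max(p for _, p in candidates)
        worst = max((c for c, p in candidates if p == worst_p),
                    key=lambda c: cols.index(c))
        log.append({"action": "drop", "term": worst, "p": float(worst_p)})
        cols.remove(worst)
    return fit, log


# ---------------------------------------------------------------------------
# single-occurrence resampling
# ---------------------------------------------------------------------------

def occurrence_resampling(tree, records: pd.DataFrame, y: pd.Series,
                          predictor: str = "elevation_m", n_iter: int = 100,
                          seed: int = 0, alpha: float = 0.05) -> dict:
    """Refit the binary phylogenetic GLMM on one random occurrence per species.

    ``y`` is the binary response indexed by species (tree tip order is taken
    from the tree).  Each iteration draws one record per species uniformly at
    random, rebuilds the predictor, refits, and records the predictor's
    p-value; the return includes the percentage of iterations with
    p < ``alpha``, the per-iteration table, and a failure tally (failed fits
    are counted, never silently dropped).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    species = list(tree.tip_labels)
    have = set(records["species"])
    missing = [s for s in species if s not in have]
    if missing:
        raise ValueError(f"species without occurrence records: {missing}")
    yv = np.asarray([y[s] for s in species], dtype=float)
    C = phylo_cov(tree)
    groups = {s: df for s, df in records.groupby("species")}
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for it in range(n_iter):
        x = np.empty(len(species))
        for i, s in enumerate(species):
            df = groups[s]
            x[i] = df[predictor].iloc[rng.integers(len(df))]
        try:
            fit = phylo_logistic_fit(C, yv, pd.DataFrame({predictor: x}))
            rows.append({"iter": it, "coef": float(fit.params[predictor]),
                         "p": float(fit.pvalues[predictor]),
                         "s2": fit.s2, "failed": False})
        except Exception as exc:
            n_failed += 1
            rows.append({"iter": it, "coef": np.nan, "p": np.nan,
                         "s2": np.nan, "failed": True, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    pct = 100.0 * float((ok["p"] < alpha).sum()) / n_iter
    return {"pct_significant": pct, "table": table, "n_failed": n_failed,
            "n_iter": n_iter}
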