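"""Replicated simulation studies over the synthetic generator.

These are the package's validation experiments: each runs many independent
synthetic datasets through the inference machinery and scores the results
against the generator's ground truth.

* :func:`scenario_recovery_study` — can the full pipeline (Mk fit ->
  marginal ASR -> shift paths -> verdict) recover the generating scenario?
* :func:`correlation_study` — does the correlated-evolution test prefer the
  independent model when the characters really evolved independently?
* :func:`mk_recovery_study` — how well are transition rates recovered, as a
  function of tree size?

Per-replicate seeds are drawn from a single ``numpy`` generator seeded with
the study seed, so studies are reproducible end to end.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import markov, scenario as scen, synth


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def run_scenario_replicate(scenario: str, n_tips: int, seed: int,
                           scheme_name: str = "SYM",
                           n_restarts: int = 2) -> dict | None:
    """One synthetic dataset through fit -> ASR -> scenario verdict.

    Both binary characters are fitted with the given Mk scheme (the single
    shared rate of SYM is the robust choice for a binary character on a
    150-tip tree; richer schemes are compared in the model-selection stage
    of the main pipeline).  Returns None when a character is monomorphic at
    the tips, which carries no ordering information.
    """
    spec = synth.ScenarioSpec.for_scenario(scenario, n=n_tips, seed=seed)
    tree = synth.simulate_bd_tree(spec.n, spec.birth, spec.death, spec.seed)
    hist = synth.simulate_joint_history(tree, spec)
    env, poll = hist.tip_env, hist.tip_poll
    if poll.sum() in (0, len(poll)) or env.sum() in (0, len(env)):
        return None
    sc = markov.RateScheme(k=2, name=scheme_name)
    fit_p = markov.fit_mk(tree, poll, sc, n_restarts=n_restarts, seed=seed)
    fit_e = markov.fit_mk(tree, env, sc, n_restarts=n_restarts, seed=seed + 1)
    asr_p = markov.marginal_asr(tree, poll, fit_p.q)
    asr_e = markov.marginal_asr(tree, env, fit_e.q)
    rep = scen.scenario_report(tree, poll.astype(bool), asr_p, asr_e,
                               cutoffs=(1000.0,), bin_edges=(1000.0,))
    return {
        "scenario": scenario,
        "seed": seed,
        "verdict": rep.verdicts[1000.0],
        "n_lineages": int(len(rep.table)),
        "n_shifted_tips": int(poll.sum()),
        "n_montane_tips": int(env.sum()),
    }


def scenario_recovery_study(scenario: str, n_reps: int = 50, n_tips: int = 150,
                            seed: int = 0) -> pd.DataFrame:
    """Replicate :func:`run_scenario_replicate`; adds a ``recovered`` column."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _rep_seeds(seed, n_reps):
            out = run_scenario_replicate(scenario, n_tips, int(rep_seed))
            if out is not None:
                rows.append(out)
    df = pd.DataFrame(rows)
    df["recovered"] = df["verdict"] == scenario
    return df


def recovery_rate(df: pd.DataFrame, n_reps: int) -> float:
    """Fraction of *attempted* replicates recovered (unusable ones count
    against recovery)."""
    return float(df["recovered"].sum()) / n_reps


def correlation_study(n_reps: int = 50, n_tips: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Correlated-evolution test on independently evolving characters.

    Each replicate simulates the INDEPENDENT scenario and runs the
    dependent-vs-independent product-space Mk comparison on the two binary
    characters; under the truth the independent model should usually win.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _rep_seeds(seed, n_reps):
            rep_seed = int(rep_seed)
            spec = synth.ScenarioSpec.for_scenario("INDEPENDENT", n=n_tips,
                                                   seed=rep_seed)
            tree = synth.simulate_bd_tree(spec.n, spec.birth, spec.death,
                                          spec.seed)
            hist = synth.simulate_joint_history(tree, spec)
            env, poll = hist.tip_env, hist.tip_poll
            if poll.sum() in (0, len(poll)) or env.sum() in (0, len(env)):
                continue
            res = markov.correlation_test(tree, env, poll, n_restarts=2,
                                          seed=rep_seed)
            rows.append({
                "seed": rep_seed,
                "aic_indep": res["aic_indep"],
                "aic_dep": res["aic_dep"],
                "verdict": res["verdict"],
            })
    return pd.DataFrame(rows)


def mk_recovery_study(n_reps: int = 20, tip_sizes=(50, 200), q_true: float = 0.1,
                      seed: int = 0) -> pd.DataFrame:
    """Rate recovery for a symmetric 2-state Mk model at several tree sizes.

    Simulates a character at the known rate on Yule trees, refits, and
    records the relative error of the estimate; the median error should
    shrink as tips are added.
    """
    rows = []
    sc = markov.RateScheme(k=2, name="SYM")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n_tips in tip_sizes:
            for rep_seed in _rep_seeds(seed + n_tips, n_reps):
                rep_seed = int(rep_seed)
                tree = synth.simulate_bd_tree(n_tips, 0.25, 0.0, rep_seed)
                q = sc.build_q([q_true])
                states = _simulate_mk(tree, q, rep_seed)
                if len(np.unique(states)) < 2:
                    continue
                fit = markov.fit_mk(tree, states, sc, n_restarts=2,
                                    seed=rep_seed)
                rows.append({
                    "n_tips": n_tips,
                    "q_hat": float(fit.rates[0]),
                    "rel_error": abs(float(fit.rates[0]) - q_true) / q_true,
                })
    return pd.DataFrame(rows)


def _simulate_mk(tree, q: np.ndarray, seed: int) -> np.ndarray:
    """Simulate a discrete character down the tree under rate matrix q."""
    rng = np.random.default_rng(seed)
    k = q.shape[0]
    states = np.zeros(tree.n_nodes, dtype=int)
    states[tree.root] = rng.integers(k)
    for v in range(tree.n_nodes - 2, -1, -1):
        p = markov.transition_matrices(q, np.array([tree.blen[v]]))[0]
        states[v] = rng.choice(k, p=p[states[tree.parent[v]]]
                               / p[states[tree.parent[v]]].sum())
    return states[: tree.n_tips]
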