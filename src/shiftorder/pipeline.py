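"""End-to-end orchestration: niche prep -> character coding -> model
selection -> ancestral reconstruction -> scenario verdict -> regression
battery, from a single structured configuration.

Every stage is a thin call into the corresponding module; the bundle written
to the output directory contains machine-readable CSV/JSON per stage plus a
run manifest (configuration hash, seed, row counts, timings).  Stage outputs
are content-addressed by the configuration hash: re-running with an
unchanged configuration and inputs reuses what is already on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import markov, niche, phylostats, scenario as scen
from .trees import SYNDROMES, Phylogeny, align_tree_and_traits, read_newick, \
    read_trait_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tree: str
    traits: str
    occurrences: str
    outdir: str
    cell_deg: float = niche.DEFAULT_CELL_DEG
    cutoffs: tuple = scen.DEFAULT_CUTOFFS
    tau_shift: float = 0.95
    tau_sweep: tuple = (0.90, 0.95, 0.99)
    delta: float = 0.10
    engine: str = "mk"  # mk | sse
    schemes: tuple = ("SYM", "ARD")
    root_prior: str = "fitzjohn"
    n_restarts: int = 3
    correlation_cutoff: float = 1000.0  # binarization for the correlation test
    tribe_cut_age_fraction: float = 0.5
    split_elevation: float = 1000.0
    resample_n_iter: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("tree", "traits", "occurrences"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.engine not in ("mk", "sse"):
            raise ValueError("engine must be 'mk' or 'sse'")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        d = asdict(self)
        h.update(json.dumps({k: str(v) for k, v in d.items()},
                            sort_keys=True).encode())
        for name in ("tree", "traits", "occurrences"):
            h.update(Path(getattr(self, name)).read_bytes())
        return h.hexdigest()[:16]


def _age_cut_clades(tree: Phylogeny, age: float) -> np.ndarray:
    """Assign each tip to the maximal clade whose stem crosses ``age``.

    Used as an operational stand-in for taxonomic tribes on synthetic trees:
    cutting the tree at a fixed age partitions the tips into clades.
    """
    ages = tree.ages()
    group = np.full(tree.n_tips, -1, dtype=int)
    tips_below = tree.subtree_tips()
    label = 0
    for v in range(tree.n_nodes - 1, -1, -1):
        p = tree.parent[v]
        if p == -1:
            continue
        if ages[v] <= age < ages[p]:
            for t in tips_below[v]:
                group[t] = label
            label += 1
    group[group == -1] = np.arange(label, label + (group == -1).sum())
    return group


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results bundle (also written
    to ``config.outdir``).

    On a stage failure the bundle is returned marked partial with the
    failing stage named; downstream stages are skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.content_hash()
    manifest = {"config": {k: str(v) for k, v in asdict(config).items()},
                "config_hash": cfg_hash, "seed": config.seed,
                "stages": {}, "partial": False}
    bundle: dict = {"manifest": manifest}
    prev_manifest = None
    mpath = outdir / "manifest.json"
    if mpath.exists():
        try:
            prev_manifest = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            prev_manifest = None
    cache_ok = prev_manifest is not None and \
        prev_manifest.get("config_hash") == cfg_hash

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            manifest["partial"] = True
            manifest["failed_stage"] = name
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s", name, exc)
            raise StageFailure(name, exc)
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        return out

    def cached_csv(name, compute):
        path = outdir / f"{name}.csv"
        if cache_ok and path.exists():
            manifest["stages"][name] = {"status": "cached"}
            return pd.read_csv(path)
        df = stage(name, compute)
        df.to_csv(path, index=False)
        return df

    try:
        # -- inputs -------------------------------------------------------
        def load():
            tree = read_newick(config.tree)
            traits = read_trait_table(config.traits)
            occ = niche.read_occurrences(config.occurrences)
            return tree, traits, occ

        tree, traits, occ = stage("load", load)

        # -- niche preparation -------------------------------------------
        def prep():
            records = niche.dedup_exact(occ)
            records = niche.grid_subsample(records, config.cell_deg)
            return niche.summarize_species(records), records

        summaries, records = stage("niche", prep)
        summaries.to_csv(outdir / "species_niche_summaries.csv", index=False)

        # -- alignment and character coding ------------------------------
        def code():
            common = set(summaries["species"])
            tr = traits[traits["species"].isin(common)]
            t2, tr2 = align_tree_and_traits(tree, tr)
            tr2 = tr2.set_index("species").loc[t2.tip_labels].reset_index()
            sm2 = summaries.set_index("species").loc[t2.tip_labels].reset_index()
            synd = np.array([SYNDROMES.index(s) for s in tr2["syndrome"]])
            elev_bin = np.array([niche.ELEVATION_BINS.index(b)
                                 for b in sm2["elevation_bin"]])
            return t2, tr2, sm2, synd, elev_bin

        tree_a, traits_a, summ_a, synd_states, elev_states = stage("code", code)

        # -- model selection and ASR for both characters ------------------
        def fit_char(states, seed_offset):
            schemes = [markov.RateScheme(k=4, name=s) for s in config.schemes]
            best, table = markov.fit_models_and_select(
                tree_a, states, schemes, engine=config.engine,
                root_prior=config.root_prior, n_restarts=config.n_restarts,
                seed=config.seed + seed_offset)
            asr = markov.marginal_asr(tree_a, states, best.q, config.root_prior)
            return best, table, asr

        (best_poll, table_poll, asr_poll) = stage(
            "fit_pollination", lambda: fit_char(synd_states, 10))
        (best_elev, table_elev, asr_elev) = stage(
            "fit_elevation", lambda: fit_char(elev_states, 20))
        table_poll.drop(columns=["rates"]).to_csv(
            outdir / "model_selection_pollination.csv", index=False)
        table_elev.drop(columns=["rates"]).to_csv(
            outdir / "model_selection_elevation.csv", index=False)
        for nm, asr in (("pollination", asr_poll), ("elevation", asr_elev)):
            pd.DataFrame(asr, columns=[f"state_{i + 1}_prob"
                                       for i in range(asr.shape[1])]) \
                .assign(node_id=np.arange(len(asr))) \
                .to_csv(outdir / f"asr_{nm}.csv", index=False)
        bundle.update(model_selection={"pollination": table_poll,
                                       "elevation": table_elev},
                      asr={"pollination": asr_poll, "elevation": asr_elev})

        # -- scenario classification --------------------------------------
        def scenario_stage():
            shifted = synd_states != 0
            reports = {}
            for tau in sorted(set(config.tau_sweep) | {config.tau_shift}):
                reports[tau] = scen.scenario_report(
                    tree_a, shifted, asr_poll, asr_elev,
                    cutoffs=config.cutoffs, delta=config.delta, tau_shift=tau)
            return reports

        reports = stage("scenario", scenario_stage)
        main_report = reports[config.tau_shift]
        main_report.table.to_csv(outdir / "scenario_lineages.csv", index=False)
        main_report.to_json(outdir / "scenario.json")
        sweep = pd.DataFrame([
            {"tau_shift": tau, "cutoff": c, "verdict": v}
            for tau, rep in reports.items()
            for c, v in rep.verdicts.items()])
        sweep.to_csv(outdir / "scenario_tau_sweep.csv", index=False)
        bundle.update(scenario=main_report, scenario_sweep=sweep)

        # -- correlated evolution -----------------------------------------
        def correlation():
            shifted = (synd_states != 0).astype(int)
            montane = (summ_a["median_elevation_m"].to_numpy()
                       >= config.correlation_cutoff).astype(int)
            res = markov.correlation_test(
                tree_a, montane, shifted, root_prior=config.root_prior,
                n_restarts=config.n_restarts, seed=config.seed + 30)
            return {k: v for k, v in res.items() if not k.startswith("fit_")}

        corr = stage("correlation", correlation)
        (outdir / "correlation_test.json").write_text(
            json.dumps(corr, indent=2, default=float))
        bundle.update(correlation=corr)

        # -- regression battery -------------------------------------------
        def stats_battery():
            out = {}
            elev = summ_a["median_elevation_m"].to_numpy()
            lat = summ_a["median_abs_latitude"].to_numpy()
            prec = summ_a["median_bio12_mm"].to_numpy()
            temp = summ_a["median_bio1_degC"].to_numpy()
            shifted = (synd_states != 0).astype(float)
            synd_labels = np.array([SYNDROMES[s] for s in synd_states])

            f, p = phylostats.phylo_anova(
                tree_a, elev, synd_labels, nsim=1000, seed=config.seed + 40)
            out["anova_elevation_by_syndrome"] = {"F": f, "p": p}

            X = pd.DataFrame({"elevation": elev, "latitude": lat,
                              "precipitation": prec})
            phylostats.collinearity_guard(X)
            X["elevation:latitude"] = X["elevation"] * X["latitude"]
            fit, log = phylostats.stepwise_reduce(
                tree_a, shifted, X, model="logistic")
            out["pglmm_shifted"] = {"summary": fit.summary().to_dict(),
                                    "s2": fit.s2, "steps": log}

            # operational tribes: clades cut at a fixed age fraction
            cut_age = config.tribe_cut_age_fraction * tree_a.ages().max()
            tribes = _age_cut_clades(tree_a, cut_age)
            shifted_tribe = np.isin(
                tribes, np.unique(tribes[shifted.astype(bool)]))
            bee = ~shifted.astype(bool)
            res_ts = {}
            if 0 < (bee & shifted_tribe).sum() < bee.sum():
                sub = np.flatnonzero(bee)
                Csub = phylostats.phylo_cov(tree_a)[np.ix_(sub, sub)]
                grp = shifted_tribe[sub].astype(int)
                d, pv = phylostats.phylo_two_sample(Csub, elev[sub], grp)
                res_ts["elevation_bee_shifted_vs_nonshifted_tribes"] = \
                    {"difference": d, "p": pv}
                hi = elev[sub] >= config.split_elevation
                for name, mask in (("below", ~hi), ("above", hi)):
                    if len(set(grp[mask])) == 2:
                        Cm = Csub[np.ix_(np.flatnonzero(mask),
                                         np.flatnonzero(mask))]
                        for var, vals in (("temperature", temp[sub][mask]),
                                          ("precipitation", prec[sub][mask])):
                            d2, p2 = phylostats.phylo_two_sample(
                                Cm, vals, grp[mask])
                            res_ts[f"{var}_{name}_{int(config.split_elevation)}m"] \
                                = {"difference": d2, "p": p2}
            out["two_sample"] = res_ts

            # montane subset: does temperature separate bee from shifted?
            mont = np.flatnonzero(elev >= config.split_elevation)
            if len(mont) >= 10 and 0 < shifted[mont].sum() < len(mont):
                Cm = phylostats.phylo_cov(tree_a)[np.ix_(mont, mont)]
                Xm = pd.DataFrame({"temperature": temp[mont],
                                   "precipitation": prec[mont]})
                fitm, logm = phylostats.stepwise_reduce(
                    Cm, shifted[mont], Xm, model="logistic")
                out["pglmm_montane"] = {"summary": fitm.summary().to_dict(),
                                        "steps": logm}

            groups = pd.Series(np.where(shifted.astype(bool), "shifted", "bee"),
                               index=summ_a["species"])
            try:
                chis = niche.biome_chisq(groups, summ_a)
                out["biome_chisq"] = {
                    "chi2": chis.chi2, "df": chis.df, "p": chis.pvalue,
                    "strong_cells": [list(c) for c in chis.strong_cells]}
            except ValueError as exc:
                out["biome_chisq"] = {"skipped": str(exc)}

            # floral traits among bee-pollinated species
            beeidx = np.flatnonzero(bee)
            Cb = phylostats.phylo_cov(tree_a)[np.ix_(beeidx, beeidx)]
            tb = traits_a.iloc[beeidx]
            Xf = pd.DataFrame({"elevation": elev[beeidx],
                               "latitude": lat[beeidx],
                               "precipitation": prec[beeidx]})
            Xf["elevation:latitude"] = Xf["elevation"] * Xf["latitude"]
            for nm, vals in (
                    ("petal_length", tb["petal_length_mm"].to_numpy()),
                    ("pore_area", niche.pore_area(tb["pore_height_mm"].to_numpy(),
                                                  tb["pore_width_mm"].to_numpy()))):
                okv = np.isfinite(vals) & (vals > 0)
                fitf, logf = phylostats.stepwise_reduce(
                    Cb[np.ix_(np.flatnonzero(okv), np.flatnonzero(okv))],
                    np.log(vals[okv]), Xf[okv], model="linear")
                out[f"pglmm_log_{nm}"] = {"summary": fitf.summary().to_dict(),
                                          "sigma2": fitf.sigma2,
                                          "steps": logf}
            wall = (tb["thecal_wall"] == "ruminate").astype(float).to_numpy()
            if 0 < wall.sum() < len(wall):
                fitw, logw = phylostats.stepwise_reduce(
                    Cb, wall, Xf[["elevation", "latitude"]], model="logistic")
                out["pglmm_thecal_wall"] = {"summary": fitw.summary().to_dict(),
                                            "steps": logw}
            return out

        stats_out = stage("stats", stats_battery)
        (outdir / "stats_battery.json").write_text(
            json.dumps(stats_out, indent=2, default=float))
        bundle.update(stats=stats_out)

        # -- occurrence resampling ----------------------------------------
        def resample():
            yser = pd.Series((synd_states != 0).astype(float),
                             index=summ_a["species"])
            rec = records[records["species"].isin(summ_a["species"])]
            return phylostats.occurrence_resampling(
                tree_a, rec, yser, predictor="elevation_m",
                n_iter=config.resample_n_iter, seed=config.seed + 50)

        res = stage("resampling", resample)
        res["table"].to_csv(outdir / "resampling_iterations.csv", index=False)
        bundle.update(resampling={"pct_significant": res["pct_significant"],
                                  "n_failed": res["n_failed"]})
        manifest["resampling_pct_significant"] = res["pct_significant"]

    except StageFailure:
        pass
    finally:
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
    bundle["partial"] = manifest["partial"]
    return bundle
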