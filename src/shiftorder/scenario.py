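"""Shift-path extraction and 1:1-line scenario classification.

Given marginal ancestral reconstructions of the pollination character and of
the (binned) elevation character on the same dated tree, this module

1. identifies *shifted clades* — maximal monophyletic groups of tips that all
   carry a non-bee pollination syndrome (singletons allowed);
2. extracts, for each shifted clade, the rootward *shift path*: per node the
   probability of having shifted pollinators (x = 1 - P(bee)), the
   probability of being montane under a chosen elevation cutoff
   (y = sum of bin probabilities above the cutoff), and the node age;
3. classifies each path against the 1:1 line: an ancestral node sitting on
   the y axis with the trajectory above the line indicates that the
   environment shift preceded the pollinator shift, and vice versa;
4. aggregates per-lineage classifications into a scenario verdict
   (environment-first / pollinator-first / simultaneous) for each of the
   elevation binarization cutoffs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny

DEFAULT_CUTOFFS = (500.0, 1000.0, 1500.0)
#: left-closed upper boundaries of elevation bins E1..E4 (m)
DEFAULT_BIN_EDGES = (500.0, 1000.0, 1500.0)

AXIS_CATEGORIES = ("ON_Y_AXIS", "NEAR_ORIGIN", "ON_X_AXIS", "INTERIOR")
LINE_POSITIONS = ("ABOVE_1_1", "NEAR_1_1", "BELOW_1_1")
VERDICTS = ("ENV_FIRST", "POLL_FIRST", "SIMULTANEOUS", "UNDEFINED")


@dataclass
class ShiftedClade:
    """Maximal monophyletic group of tips with shifted pollination."""

    mrca: int
    tips: list[int]
    stem_parent: int

    @property
    def is_singleton(self) -> bool:
        return len(self.tips) == 1


@dataclass
class ShiftPath:
    """Rootward trajectory of one shifted lineage.

    ``nodes`` runs from the shift-side start node toward the root; ``x`` is
    the pollinator-shift probability, ``y`` the environment-shift (montane)
    probability under ``cutoff``, ``ages`` the node ages in Myr.
    ``reached_ancestral_state`` is False when the walk hit the root before
    finding a confidently bee-pollinated node.
    """

    lineage: str
    nodes: list[int]
    x: np.ndarray
    y: np.ndarray
    ages: np.ndarray
    cutoff: float
    tau_shift: float
    reached_ancestral_state: bool = True


def identify_shifted_clades(tree: Phylogeny, shifted_tip: np.ndarray) -> list[ShiftedClade]:
    """Maximal monophyletic all-shifted tip groups (singletons included).

    ``shifted_tip`` is a boolean array over tips (True = non-bee syndrome).
    """
    shifted_tip = np.asarray(shifted_tip, dtype=bool)
    if shifted_tip.shape != (tree.n_tips,):
        raise ValueError("need one shifted flag per tip")
    if not shifted_tip.any():
        warnings.warn("no shifted tips; returning no clades", stacklevel=2)
        return []
    all_shifted = np.zeros(tree.n_nodes, dtype=bool)
    all_shifted[: tree.n_tips] = shifted_tip
    for v in range(tree.n_tips, tree.n_nodes):
        all_shifted[v] = all(all_shifted[c] for c in tree.children[v])
    tips_below = tree.subtree_tips()
    clades = []
    for v in range(tree.n_nodes):
        if not all_shifted[v]:
            continue
        p = tree.parent[v]
        if p != -1 and all_shifted[p]:
            continue  # not maximal
        clades.append(ShiftedClade(mrca=v, tips=sorted(int(t) for t in tips_below[v]),
                                   stem_parent=int(p)))
    return clades


def montane_probability(env_probs: np.ndarray, cutoff: float,
                        bin_edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """P(above cutoff) = sum of bin probabilities strictly above the cutoff
    boundary; e.g. cutoff 1000 with 4 bins keeps E3 + E4."""
    env_probs = np.asarray(env_probs, dtype=float)
    edges = list(bin_edges)
    if env_probs.shape[-1] != len(edges) + 1:
        raise ValueError("env_probs columns must match bin count")
    lower = [0.0] + edges  # lower boundary of each bin
    keep = [i for i, lo in enumerate(lower) if lo >= cutoff and i > 0]
    if not keep:
        raise ValueError(f"cutoff {cutoff} below every bin boundary")
    return env_probs[..., keep].sum(axis=-1)


def extract_shift_path(tree: Phylogeny, clade: ShiftedClade,
                       asr_poll_shifted: np.ndarray, asr_env_montane: np.ndarray,
                       cutoff: float, tau_shift: float = 0.95) -> ShiftPath:
    """Walk rootward from a shifted clade collecting (x, y, age) per node.

    The start node is the deepest node on the clade's rootward chain with
    pollinator-shift probability >= ``tau_shift`` (the clade MRCA when it
    qualifies; the tip itself for singletons whose parent does not).  The
    walk appends each ancestor and stops at (and includes) the first node
    whose bee probability reaches ``tau_shift``; if the root is reached
    first, the path is flagged.
    """
    if not (0.5 < tau_shift <= 1.0):
        raise ValueError("tau_shift must be in (0.5, 1]")
    x_all = np.asarray(asr_poll_shifted, dtype=float)
    y_all = np.asarray(asr_env_montane, dtype=float)
    ages = tree.ages()

    # "last shared node" rule: a multi-tip clade starts at its MRCA when the
    # MRCA is confidently shifted; otherwise (and for singletons, whose MRCA
    # is the tip itself) the representative tip's values are used and the
    # walk passes through the MRCA on its way rootward.
    if x_all[clade.mrca] >= tau_shift:
        start = clade.mrca
    else:
        start = clade.tips[0]
    nodes = [start]
    reached = False
    v = tree.parent[start]
    while v != -1:
        nodes.append(v)
        if 1.0 - x_all[v] >= tau_shift:  # P(bee) >= tau
            reached = True
            break
        v = tree.parent[v]
    if not reached:
        warnings.warn(
            f"lineage {clade.mrca}: root reached before P(bee) >= {tau_shift}",
            stacklevel=2)
    label = tree.tip_labels[clade.tips[0]] if clade.is_singleton \
        else f"clade_{clade.mrca}"
    return ShiftPath(
        lineage=label,
        nodes=nodes,
        x=x_all[nodes],
        y=y_all[nodes],
        ages=ages[nodes],
        cutoff=cutoff,
        tau_shift=tau_shift,
        reached_ancestral_state=reached,
    )


def classify_lineage(path: ShiftPath, delta: float = 0.10) -> tuple[str, str]:
    """(axis category, 1:1-line position) for one shift path.

    The axis category describes the *ancestral-most* node (x_a, y_a): on the
    y axis (environment already shifted while pollination was still
    ancestral), near the origin (neither), on the x axis (pollinators already
    shifted), or interior.  The line position is the mean signed deviation
    y - x over all path nodes relative to the 1:1 line, with margin
    ``delta``.
    """
    if not (0.0 < delta < 0.5):
        raise ValueError("delta must be in (0, 0.5)")
    if len(path.nodes) == 0:
        raise ValueError("empty shift path")
    # path cleaning: consecutive duplicate points carry no extra information
    # and must not bias the trajectory mean
    pts = np.column_stack([path.x, path.y])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    path = ShiftPath(lineage=path.lineage,
                     nodes=[n for n, k in zip(path.nodes, keep) if k],
                     x=path.x[keep], y=path.y[keep], ages=path.ages[keep],
                     cutoff=path.cutoff, tau_shift=path.tau_shift,
                     reached_ancestral_state=path.reached_ancestral_state)
    x_a, y_a = float(path.x[-1]), float(path.y[-1])
    if x_a <= delta and y_a >= delta:
        axis = "ON_Y_AXIS"
    elif x_a <= delta and y_a < delta:
        axis = "NEAR_ORIGIN"
    elif x_a > delta and y_a < delta:
        axis = "ON_X_AXIS"
    else:
        axis = "INTERIOR"
    dev = float(np.mean(path.y - path.x))
    if dev > delta:
        line = "ABOVE_1_1"
    elif dev < -delta:
        line = "BELOW_1_1"
    else:
        line = "NEAR_1_1"
    return axis, line


def _verdict(rows: pd.DataFrame) -> str:
    """Majority rule over concordant (line, axis) evidence.

    The 1:1-line position carries the ordering signal: a trajectory above
    the line means the environment-shift probability exceeded the
    pollinator-shift probability along the lineage's history, and vice
    versa.  The axis category of the ancestral-most node must not contradict
    it: an environment-first vote requires a trajectory above the line with
    an ancestor on the y axis or at the origin (the walk can end at a node
    older than the environment shift itself), a pollinator-first vote
    requires a trajectory below the line with an ancestor on the x axis or
    at the origin.  A strict majority of lineages decides; otherwise the
    scenario is called simultaneous.
    """
    n = len(rows)
    if n == 0:
        return "UNDEFINED"
    env = (rows["axis"].isin(["ON_Y_AXIS", "NEAR_ORIGIN"])
           & (rows["line"] == "ABOVE_1_1")).sum()
    poll = (rows["axis"].isin(["ON_X_AXIS", "NEAR_ORIGIN"])
            & (rows["line"] == "BELOW_1_1")).sum()
    if env > n / 2:
        return "ENV_FIRST"
    if poll > n / 2:
        return "POLL_FIRST"
    return "SIMULTANEOUS"


@dataclass
class ScenarioReport:
    """Per-cutoff lineage classifications, counts and verdicts."""

    table: pd.DataFrame  # one row per lineage x cutoff
    verdicts: dict  # cutoff -> verdict
    delta: float
    tau_shift: float

    def counts(self, cutoff: float) -> pd.Series:
        sub = self.table[self.table["cutoff"] == cutoff]
        return sub.groupby(["axis", "line"]).size()

    def to_json(self, path=None) -> str:
        payload = {
            "delta": self.delta,
            "tau_shift": self.tau_shift,
            "verdicts": {str(k): v for k, v in self.verdicts.items()},
            "lineages": self.table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def scenario_report(tree: Phylogeny, shifted_tip, asr_poll: np.ndarray,
                    asr_env: np.ndarray, cutoffs=DEFAULT_CUTOFFS,
                    delta: float = 0.10, tau_shift: float = 0.95,
                    bin_edges=DEFAULT_BIN_EDGES) -> ScenarioReport:
    """Classify every shifted lineage under every elevation cutoff.

    ``asr_poll`` has one probability row per node over the pollination states
    with the bee state in column 0; ``asr_env`` has one row per node over the
    elevation bins (len(bin_edges) + 1 columns, or 2 columns with a single
    edge for pre-binarized characters).
    """
    asr_poll = np.asarray(asr_poll, dtype=float)
    asr_env = np.asarray(asr_env, dtype=float)
    x_all = 1.0 - asr_poll[:, 0]
    clades = identify_shifted_clades(tree, shifted_tip)
    rows = []
    for cutoff in cutoffs:
        y_all = montane_probability(asr_env, cutoff, bin_edges)
        for clade in clades:
            path = extract_shift_path(tree, clade, x_all, y_all, cutoff,
                                      tau_shift)
            axis, line = classify_lineage(path, delta)
            rows.append({
                "cutoff": cutoff,
                "lineage": path.lineage,
                "mrca": clade.mrca,
                "n_tips": len(clade.tips),
                "start_age": float(path.ages[0]),
                "end_age": float(path.ages[-1]),
                "x_ancestral": float(path.x[-1]),
                "y_ancestral": float(path.y[-1]),
                "mean_dev": float(np.mean(path.y - path.x)),
                "axis": axis,
                "line": line,
                "reached_ancestral_state": path.reached_ancestral_state,
            })
    table = pd.DataFrame(rows, columns=[
        "cutoff", "lineage", "mrca", "n_tips", "start_age", "end_age",
        "x_ancestral", "y_ancestral", "mean_dev", "axis", "line",
        "reached_ancestral_state"])
    verdicts = {}
    for cutoff in cutoffs:
        verdicts[float(cutoff)] = _verdict(table[table["cutoff"] == cutoff])
    return ScenarioReport(table=table, verdicts=verdicts, delta=delta,
                          tau_shift=tau_shift)
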