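#!/usr/bin/env python
"""Plot the shift-path trajectories against the 1:1 line.

One panel per montane cutoff (500 / 1000 / 1500 m): x = pollinator-shift
probability, y = environment-shift probability per node along each shifted
lineage's rootward path; trajectories above the dashed 1:1 line indicate
environment shifts preceding pollinator shifts.

Requires 01 and 02 to have been run.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from shiftorder import niche, scenario as scen, trees  # noqa: E402
from shiftorder.trees import SYNDROMES, read_trait_table  # noqa: E402


def main():
    run = ROOT / "results" / "run"
    tree = trees.read_newick(ROOT / "results" / "data" / "tree.nwk")
    summaries = pd.read_csv(run / "species_niche_summaries.csv")
    traits = read_trait_table(ROOT / "results" / "data" / "traits.csv")
    traits = traits.set_index("species").loc[tree.tip_labels]
    asr_poll = pd.read_csv(run / "asr_pollination.csv").filter(like="state_").to_numpy()
    asr_env = pd.read_csv(run / "asr_elevation.csv").filter(like="state_").to_numpy()

    shifted = (traits["syndrome"] != "bee").to_numpy()
    x_all = 1.0 - asr_poll[:, 0]
    clades = scen.identify_shifted_clades(tree, shifted)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, cutoff in zip(axes, (500.0, 1000.0, 1500.0)):
        y_all = scen.montane_probability(asr_env, cutoff)
        for clade in clades:
            path = scen.extract_shift_path(tree, clade, x_all, y_all, cutoff)
            ax.plot(path.x, path.y, "-o", ms=3, alpha=0.7)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.set_title(f"montane > {cutoff:.0f} m")
        ax.set_xlabel("P(pollinator shifted)")
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
    axes[0].set_ylabel("P(environment shifted)")
    fig.tight_layout()
    out = ROOT / "results" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    fig.savefig(out / "shift_paths_by_cutoff.png", dpi=150)
    print(f"plotted {len(clades)} shifted lineages per cutoff ->",
          out / "shift_paths_by_cutoff.png")


if __name__ == "__main__":
    main()
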