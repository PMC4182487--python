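#!/usr/bin/env python
"""Fit psychometric functions to every simulated block.

Reads results/responses.csv (from 03), fits the lapse-bounded cumulative
Gaussian per (subject, condition, velocity) with parametric-bootstrap 95%
confidence limits, writes results/fits.csv and the group summary
(means and between-participants standard errors), and plots the group
mean PSE and beta per condition and velocity.
"""

import sys
from pathlib import Path

import pandas as pd

from vasmotion.psychometrics import summarize_group
from vasmotion.study import fit_study

OUT = Path("results")
N_BOOT = 200
SEED = 7


def _plot(group: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for measure, ax in zip(("pse", "beta"), axes):
        for cond, cell in group.groupby("condition"):
            cell = cell.sort_values("velocity")
            ax.errorbar(cell["velocity"], cell[f"{measure}_mean"],
                        yerr=cell[f"{measure}_se"], marker="o", capsize=3,
                        label=cond)
        ax.set_xlabel("velocity (deg/s)")
        ax.set_ylabel(f"group {measure.upper() if measure == 'pse' else measure} (deg)")
    axes[0].axhline(0.0, color="k", lw=0.5)
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "group_means.png", dpi=150)
    print(f"wrote {OUT / 'group_means.png'}")


def main() -> None:
    responses = pd.read_csv(OUT / "responses.csv")
    fits = fit_study(responses, n_boot=N_BOOT, seed=SEED)
    fits.to_csv(OUT / "fits.csv", index=False)
    print(f"fitted {len(fits)} blocks "
          f"({int(fits.converged.sum())} converged) -> {OUT / 'fits.csv'}")

    group = summarize_group(fits)
    group.to_csv(OUT / "group_summary.csv", index=False)
    print(group.round(3).to_string(index=False))
    try:
        _plot(group)
    except ImportError:
        print("matplotlib not available; skipping the figure")


if __name__ == "__main__":
    sys.exit(main())
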