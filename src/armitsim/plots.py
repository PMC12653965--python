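"""Convenience plots for scored tables (group bar charts, KDE curves)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import STAGE_ORDER


def plot_stage_success(stage_summary: pd.DataFrame, path=None, ax=None):
    """Grouped bar chart of mean success rate per stage and condition cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = (stage_summary.groupby(["radiation_group", "sleep_condition", "stage"])
             ["success_rate"].agg(["mean", "sem", "count"]).reset_index())
    labels = sorted({(g, c) for g, c in
                     zip(cells["radiation_group"], cells["sleep_condition"])})
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / max(len(labels), 1)
    x = np.arange(len(STAGE_ORDER))
    for i, (group, cond) in enumerate(labels):
        sub = cells[(cells["radiation_group"] == group)
                    & (cells["sleep_condition"] == cond)].set_index("stage")
        means = [sub["mean"].get(s, np.nan) for s in STAGE_ORDER]
        sems = [sub["sem"].get(s, np.nan) for s in STAGE_ORDER]
        ax.bar(x + i * width, means, width, yerr=sems, capsize=3,
               label=f"{group}/{cond}")
    ax.axhline(0.5, ls="-", c="gray", lw=0.8)
    ax.axhline(0.25, ls="--", c="gray", lw=0.8)
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels(STAGE_ORDER)
    ax.set_ylabel("success rate")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_kde(kde_result, path=None, ax=None):
    """Line plot of a KDE density over its evaluation grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(kde_result.grid, kde_result.density)
    ax.set_xlabel("success rate")
    ax.set_ylabel("density")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
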