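"""Minimal SuperPlot scaffolding.

Draws individual data points color-coded by biological replicate with the
replicate means overlaid as triangles, the convention that keeps
pseudoreplication visible in per-field measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reportstats import superplot_summary, validate_table

__all__ = ["superplot"]


def superplot(table: pd.DataFrame, ax=None, jitter: float = 0.12, seed: int = 0):
    """SuperPlot of a long-format measurement table.

    Parameters
    ----------
    table : DataFrame
        Columns ``condition``, ``replicate``, ``value``.
    ax : matplotlib Axes, optional
        Target axes (a new figure is created when omitted).
    jitter : float
        Horizontal jitter half-width for individual points.

    Returns the axes.
    """
    import matplotlib.pyplot as plt

    validate_table(table)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * table["condition"].nunique(), 3.2))
    rng = np.random.default_rng(seed)
    conditions = list(pd.unique(table["condition"]))
    replicates = list(pd.unique(table["replicate"]))
    cmap = plt.get_cmap("tab10")
    colors = {rep: cmap(i % 10) for i, rep in enumerate(replicates)}

    for x, cond in enumerate(conditions):
        sub = table[table["condition"] == cond]
        xs = x + rng.uniform(-jitter, jitter, size=len(sub))
        ax.scatter(
            xs,
            sub["value"],
            c=[colors[r] for r in sub["replicate"]],
            s=14,
            alpha=0.6,
            linewidths=0,
        )
    rep_means = superplot_summary(table).replicate_means
    for x, cond in enumerate(conditions):
        sub = rep_means[rep_means["condition"] == cond]
        ax.scatter(
            np.full(len(sub), x),
            sub["mean"],
            marker="^",
            s=90,
            c=[colors[r] for r in sub["replicate"]],
            edgecolors="black",
            zorder=3,
        )
    ax.set_xticks(range(len(conditions)), conditions)
    ax.set_ylabel("value")
    return ax
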