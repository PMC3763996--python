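"""Interval plots of posterior marginal means (level vs mean with 95% CI)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .bayes import GRAND_MEAN_LABEL

__all__ = ["interval_plot"]


def interval_plot(
    marginal_means: pd.DataFrame,
    ax: plt.Axes | None = None,
    title: str | None = None,
    color_by: dict[str, str] | None = None,
):
    """Dot-and-whisker plot of marginal means with their credible intervals.

    The grand-mean row is drawn as a horizontal reference line.
    ``color_by`` optionally maps level labels to matplotlib colors (e.g.
    by phylogenetic lineage).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    levels = marginal_means.loc[marginal_means["level"] != GRAND_MEAN_LABEL]
    grand = marginal_means.loc[marginal_means["level"] == GRAND_MEAN_LABEL]
    x = range(len(levels))
    colors = [
        (color_by or {}).get(lv, "C0") for lv in levels["level"]
    ]
    for xi, (_, row), c in zip(x, levels.iterrows(), colors):
        ax.errorbar(
            xi, row["mean"],
            yerr=[[row["mean"] - row["ci_lower"]], [row["ci_upper"] - row["mean"]]],
            fmt="o", color=c, capsize=3,
        )
    if len(grand):
        ax.axhline(float(grand["mean"].iloc[0]), ls="--", lw=1, color="grey",
                   label="grand mean")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(list(x))
    ax.set_xticklabels(levels["level"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("% samples active")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax
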