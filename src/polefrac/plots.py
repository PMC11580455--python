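"""Figure-ready plots: pole-2 vs pole-1 scatter and category bar diagram."""

from __future__ import annotations

import pandas as pd

from .population import PopulationSummary, _CATEGORIES


def scatter_poles(table: pd.DataFrame, ax=None, mean_point=None):
    """Scatter of pole-2 % against pole-1 % with the symmetry line.

    ``table`` comes from :func:`polefrac.population.scatter_table`;
    ``mean_point`` optionally marks the population mean polar fractions.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for rep, grp in table.groupby("replicate"):
        ax.scatter(grp["pole1_pct"], grp["pole2_pct"], s=8, alpha=0.6,
                   label=f"replicate {rep}")
    lim = max(100.0, float(table[["pole1_pct", "pole2_pct"]].max().max() if len(table) else 100))
    ax.plot([0, lim], [0, lim], color="black", lw=1)  # symmetry line
    if mean_point is not None:
        ax.scatter([mean_point[0]], [mean_point[1]], color="limegreen", s=60,
                   zorder=3, label="mean (all cells)")
    ax.set_xlabel("% total fluorescence at pole 1")
    ax.set_ylabel("% total fluorescence at pole 2")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.legend(fontsize=7)
    return ax


def category_bars(summaries: list[PopulationSummary], ax=None):
    """Stacked bar diagram of localization-category percentages per replicate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    xs = range(len(summaries))
    bottoms = [0.0] * len(summaries)
    for cat in _CATEGORIES:
        vals = [s.pct_per_category[cat] for s in summaries]
        ax.bar(xs, vals, bottom=bottoms, label=cat.replace("_", " "))
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_xticks(list(xs))
    ax.set_xticklabels([s.replicate for s in summaries], rotation=45)
    ax.set_ylabel("% of cells")
    ax.legend(fontsize=7)
    return ax
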