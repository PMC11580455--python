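"""Population-level aggregation of per-cell quantifications and statistics.

Snapshot experiments quantify hundreds of cells across (typically three)
biological replicates.  This module aggregates the per-cell table produced
by :mod:`polefrac.quantify` into per-replicate summaries — the percentage
of cells in each localization category and the mean polar / cytoplasmic
fluorescence fractions, computed over all cells including those without
clusters — plus a pooled summary whose means are the unweighted mean of the
replicate means (matching the convention of reporting "the mean of all
experiments"; cell-weighted pooling is available as an option).

It also provides the scatter-plot table (percentage of total fluorescence
at pole 2 against pole 1, for cells with at least one cluster) and the
two-tailed Student's t-test for samples with equal variances used for
significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .quantify import Category

__all__ = [
    "PopulationSummary",
    "aggregate",
    "scatter_table",
    "t_test_equal_var",
]

_CATEGORIES = [c.value for c in Category]


@dataclass
class PopulationSummary:
    """Category percentages and mean fluorescence fractions for one replicate
    (or for the pooled population, ``replicate='pooled'``)."""

    replicate: str
    n_cells: int
    pct_per_category: dict[str, float]
    mean_polar_pct: float        # mean of pole1_pct + pole2_pct over all cells
    mean_cytoplasmic_pct: float  # mean cytoplasmic percentage over all cells
    strain: str | None = None

    def as_row(self) -> dict:
        row = {"strain": self.strain, "replicate": self.replicate,
               "n_cells": self.n_cells,
               "mean_polar_pct": self.mean_polar_pct,
               "mean_cytoplasmic_pct": self.mean_cytoplasmic_pct}
        for cat in _CATEGORIES:
            row[f"pct_{cat}"] = self.pct_per_category[cat]
        return row


def _summarize(cells: pd.DataFrame, replicate: str,
               strain: str | None) -> PopulationSummary:
    n = len(cells)
    pct = {cat: 100.0 * float((cells["category"] == cat).sum()) / n
           for cat in _CATEGORIES}
    polar = (cells["pole1_pct"] + cells["pole2_pct"]).mean()
    return PopulationSummary(
        replicate=replicate, n_cells=n, pct_per_category=pct,
        mean_polar_pct=float(polar),
        mean_cytoplasmic_pct=float(cells["cytoplasmic_pct"].mean()),
        strain=strain,
    )


def aggregate(cells: pd.DataFrame, replicate_labels=None, strain: str | None = None,
              pooling: str = "replicate",
              ) -> tuple[list[PopulationSummary], PopulationSummary]:
    """Aggregate per-cell quantifications into replicate and pooled summaries.

    ``cells`` is the table from :func:`polefrac.quantify.quantify_image`
    (cells with and without clusters are all included, as required for the
    mean polar and cytoplasmic fractions).  ``replicate_labels`` is an
    array-like parallel to the rows (or the name of a column in ``cells``);
    omitted, all cells form a single replicate.  The pooled summary averages
    replicate summaries with equal weight (``pooling='replicate'``) or over
    all cells directly (``pooling='cells'``).  Empty replicates are excluded
    with a warning.
    """
    if len(cells) == 0:
        raise ValidationError("aggregate needs at least one cell")
    if pooling not in ("replicate", "cells"):
        raise ValidationError("pooling must be 'replicate' or 'cells'")
    cells = cells.copy()
    if replicate_labels is None:
        cells["_rep"] = "1"
    elif isinstance(replicate_labels, str):
        cells["_rep"] = cells[replicate_labels].astype(str)
    else:
        labels = np.asarray(replicate_labels)
        if labels.size != len(cells):
            raise ValidationError("replicate_labels must match the number of cells")
        cells["_rep"] = labels.astype(str)

    summaries = [
        _summarize(grp, rep, strain)
        for rep, grp in cells.groupby("_rep", sort=True)
        if len(grp) > 0
    ]
    if pooling == "cells":
        pooled = _summarize(cells, "pooled", strain)
    else:
        pooled = PopulationSummary(
            replicate="pooled",
            n_cells=int(sum(s.n_cells for s in summaries)),
            pct_per_category={
                cat: float(np.mean([s.pct_per_category[cat] for s in summaries]))
                for cat in _CATEGORIES
            },
            mean_polar_pct=float(np.mean([s.mean_polar_pct for s in summaries])),
            mean_cytoplasmic_pct=float(
                np.mean([s.mean_cytoplasmic_pct for s in summaries])
            ),
            strain=strain,
        )
    return summaries, pooled


def summary_table(summaries: list[PopulationSummary],
                  pooled: PopulationSummary | None = None) -> pd.DataFrame:
    """Replicate summaries (plus optional pooled row) as a flat table."""
    rows = [s.as_row() for s in summaries]
    if pooled is not None:
        rows.append(pooled.as_row())
    return pd.DataFrame(rows)


def scatter_table(cells: pd.DataFrame, replicate_labels=None) -> pd.DataFrame:
    """Pole-2 vs pole-1 percentage table for all cells with polar cluster(s).

    One row per clustered cell (category != diffuse) with columns
    ``pole1_pct``, ``pole2_pct``, ``replicate``, ``category``; every row
    satisfies pole1_pct >= pole2_pct, so points lie on one side of the
    symmetry line of the scatter plot.
    """
    cells = cells.copy()
    if replicate_labels is None:
        cells["replicate"] = "1"
    elif isinstance(replicate_labels, str):
        cells["replicate"] = cells[replicate_labels].astype(str)
    else:
        cells["replicate"] = np.asarray(replicate_labels).astype(str)
    clustered = cells[cells["category"] != Category.DIFFUSE.value]
    return clustered[["pole1_pct", "pole2_pct", "replicate", "category"]].reset_index(
        drop=True
    )


def t_test_equal_var(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Student's t-test for two samples with equal variances.

    Pooled-variance t statistic with ``n_a + n_b - 2`` degrees of freedom.
    With zero pooled variance the test is degenerate: equal means give
    ``(0.0, 1.0)``; unequal means raise :class:`DegenerateDataError`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    pooled_var = (a.var(ddof=1) * (a.size - 1) + b.var(ddof=1) * (b.size - 1))
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t undefined"
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
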