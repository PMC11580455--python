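"""Polar cluster detection, asymmetry index and localization classification.

For each segmented rod cell the pipeline measures how much of the total
cellular fluorescence sits in clusters at the two cell poles.  A polar
cluster is a connected group of at least ``min_size`` pixels inside a polar
cap whose mean fluorescence exceeds the mean cytoplasmic fluorescence by at
least ``k_sd`` cytoplasmic standard deviations (defaults 3 pixels and 2 SD).
Pole 1 is, by definition, the pole with the higher total cluster
fluorescence.  For cells with at least one cluster the asymmetry index

    omega = (pole1 - pole2) / (pole1 + pole2)

ranges from 0 (perfectly symmetric bipolar) to 1 (strictly unipolar), and
cells are binned as unipolar (omega > 0.9), bipolar asymmetric
(0.9 >= omega >= 0.2) or bipolar symmetric (omega < 0.2); cells with no
cluster are classified as diffuse.

Cytoplasmic statistics are computed over the mid-cell pixels (the cell
minus both polar caps), which avoids defining "cytoplasm" circularly as
"whatever is not in a cluster".  All statistics are computed on
background-subtracted intensities; the population SD convention (divisor
n) is used for the cytoplasmic SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateDataError, QuantificationError, ValidationError
from .geometry import CellRegion, PolarCaps, analyze_mask

__all__ = [
    "Category",
    "PolarCluster",
    "CellQuantification",
    "estimate_background",
    "cytoplasmic_stats",
    "detect_polar_clusters",
    "assign_poles",
    "asymmetry_index",
    "classify_localization",
    "quantify_cell",
    "quantify_image",
]

_STRUCT8 = np.ones((3, 3), bool)


class Category(str, Enum):
    """Four-way localization pattern of a cell's fluorescence."""

    UNIPOLAR = "unipolar"
    BIPOLAR_ASYMMETRIC = "bipolar_asymmetric"
    BIPOLAR_SYMMETRIC = "bipolar_symmetric"
    DIFFUSE = "diffuse"


@dataclass
class PolarCluster:
    """A detected connected polar pixel component."""

    cell_label: int
    cap: str                      # "A" or "B"
    rows: np.ndarray
    cols: np.ndarray
    integrated_fluorescence: float  # background-subtracted sum over pixels
    mean_fluorescence: float

    @property
    def n_pixels(self) -> int:
        return self.rows.size


@dataclass
class CellQuantification:
    """Per-cell fluorescence totals, percentages, omega and category."""

    cell_label: int
    total_fluorescence: float
    pole1_fluorescence: float
    pole2_fluorescence: float
    pole1_pct: float
    pole2_pct: float
    cytoplasmic_pct: float
    omega: float | None
    category: Category
    pole1_cap: str | None = None
    n_clusters: int = 0


def estimate_background(image: np.ndarray, mask: np.ndarray) -> float:
    """Median intensity of the non-cell pixels."""
    image = np.asarray(image, dtype=float)
    bg = image[np.asarray(mask) == 0]
    if bg.size == 0:
        raise ValidationError("mask covers the entire image; no background pixels")
    return float(np.median(bg))


def cytoplasmic_stats(cell: CellRegion, image: np.ndarray, caps: PolarCaps,
                      background: float = 0.0) -> tuple[float, float]:
    """Mean and population SD of background-subtracted mid-cell fluorescence.

    The mid-cell region is the cell minus both polar caps; an empty mid-cell
    means the cell cannot provide a cytoplasmic reference and is excluded.
    """
    mid = caps.mid
    if not mid.any():
        raise QuantificationError(
            f"cell {cell.label}: empty mid-cell region", label=cell.label
        )
    vals = np.asarray(image, dtype=float)[cell.rows[mid], cell.cols[mid]] - background
    return float(vals.mean()), float(vals.std())  # population SD (divisor n)


def detect_polar_clusters(cell: CellRegion, image: np.ndarray, caps: PolarCaps,
                          background: float = 0.0, k_sd: float = 2.0,
                          min_size: int = 3,
                          cyt_stats: tuple[float, float] | None = None
                          ) -> list[PolarCluster]:
    """Detect polar clusters in both caps of one cell.

    Within each cap, seed pixels are those whose background-subtracted value
    strictly exceeds ``mean + k_sd * SD`` of the cytoplasm; seeds are grouped
    into 8-connected components, and components are kept if they have at
    least ``min_size`` pixels and a component mean of at least the same
    threshold.  With a perfectly uniform cell (SD = 0) no pixel exceeds the
    threshold and no cluster is reported.
    """
    if cyt_stats is None:
        cyt_stats = cytoplasmic_stats(cell, image, caps, background)
    mean, sd = cyt_stats
    thresh = mean + k_sd * sd
    image = np.asarray(image, dtype=float)

    clusters: list[PolarCluster] = []
    for cap_name, cap_sel in (("A", caps.cap_a), ("B", caps.cap_b)):
        if not cap_sel.any():
            continue
        rr, cc = cell.rows[cap_sel], cell.cols[cap_sel]
        vals = image[rr, cc] - background
        seeds = vals > thresh
        if not seeds.any():
            continue
        # label seed pixels on a local raster to find 8-connected components
        r0, c0 = rr.min(), cc.min()
        local = np.zeros((rr.max() - r0 + 1, cc.max() - c0 + 1), bool)
        local[rr[seeds] - r0, cc[seeds] - c0] = True
        labelled, n = ndimage.label(local, structure=_STRUCT8)
        comp_of_pixel = labelled[rr - r0, cc - c0]
        for comp in range(1, n + 1):
            member = comp_of_pixel == comp
            if member.sum() < min_size:
                continue
            comp_mean = float(vals[member].mean())
            if comp_mean < thresh:
                continue
            clusters.append(PolarCluster(
                cell_label=cell.label,
                cap=cap_name,
                rows=rr[member],
                cols=cc[member],
                integrated_fluorescence=float(vals[member].sum()),
                mean_fluorescence=comp_mean,
            ))
    return clusters


def assign_poles(clusters: list[PolarCluster]) -> tuple[float, float, str | None]:
    """Sum cluster fluorescence per cap and assign pole 1 to the brighter pole.

    Returns ``(pole1_fluorescence, pole2_fluorescence, pole1_cap)``.  An
    exact tie is broken deterministically in favour of cap A (the pole at
    arc coordinate 0).  With no clusters both totals are 0 and the cap is
    None.
    """
    total_a = sum(c.integrated_fluorescence for c in clusters if c.cap == "A")
    total_b = sum(c.integrated_fluorescence for c in clusters if c.cap == "B")
    if total_a == 0.0 and total_b == 0.0 and not clusters:
        return 0.0, 0.0, None
    if total_b > total_a:
        return float(total_b), float(total_a), "B"
    return float(total_a), float(total_b), "A"


def asymmetry_index(pole1_fluorescence: float, pole2_fluorescence: float) -> float:
    """Asymmetry index omega = (pole1 - pole2) / (pole1 + pole2).

    Requires ``pole1 >= pole2 >= 0`` and ``pole1 > 0``; a cell with no polar
    fluorescence at all is diffuse and omega is undefined for it.
    """
    if pole2_fluorescence < 0 or pole1_fluorescence < pole2_fluorescence:
        raise ValidationError(
            f"need pole1 >= pole2 >= 0, got ({pole1_fluorescence}, {pole2_fluorescence})"
        )
    if pole1_fluorescence <= 0:
        raise DegenerateDataError("omega undefined: no polar fluorescence (diffuse cell)")
    return (pole1_fluorescence - pole2_fluorescence) / (
        pole1_fluorescence + pole2_fluorescence
    )


def classify_localization(omega: float | None) -> Category:
    """Bin a cell into one of the four localization categories.

    ``omega is None`` means no polar cluster was detected (diffuse).  The
    boundary values fall in the bipolar-asymmetric bin: unipolar requires
    omega strictly above 0.9, and bipolar symmetric strictly below 0.2.
    """
    if omega is None:
        return Category.DIFFUSE
    if not -1e-9 <= omega <= 1 + 1e-9:
        raise ValidationError(f"omega must lie in [0, 1], got {omega}")
    omega = min(max(omega, 0.0), 1.0)
    if omega > 0.9:
        return Category.UNIPOLAR
    if omega >= 0.2:
        return Category.BIPOLAR_ASYMMETRIC
    return Category.BIPOLAR_SYMMETRIC


def quantify_cell(cell: CellRegion, image: np.ndarray, caps: PolarCaps,
                  background: float = 0.0, k_sd: float = 2.0, min_size: int = 3,
                  subtract_cytoplasm: bool = False) -> CellQuantification:
    """Full per-cell quantification: totals, pole percentages, omega, category.

    The total is the background-subtracted sum over all cell pixels; pole
    percentages are cluster fluorescence as a percentage of that total, and
    the cytoplasmic percentage is the remainder, so the three always sum to
    100.  By default cluster fluorescence is the raw background-subtracted
    sum over cluster pixels; with ``subtract_cytoplasm`` the local diffuse
    contribution (cytoplasmic mean x cluster area) is removed first.
    """
    image = np.asarray(image, dtype=float)
    total = float((image[cell.rows, cell.cols] - background).sum())
    if total <= 0:
        raise QuantificationError(
            f"cell {cell.label}: non-positive total fluorescence", label=cell.label
        )
    stats = cytoplasmic_stats(cell, image, caps, background)
    clusters = detect_polar_clusters(
        cell, image, caps, background, k_sd=k_sd, min_size=min_size, cyt_stats=stats
    )
    if subtract_cytoplasm:
        cyt_mean = stats[0]
        for c in clusters:
            c.integrated_fluorescence = max(
                c.integrated_fluorescence - cyt_mean * c.n_pixels, 0.0
            )
    pole1, pole2, pole1_cap = assign_poles(clusters)
    if pole1 > 0:
        omega: float | None = asymmetry_index(pole1, pole2)
    else:
        omega, pole1_cap = None, None
    category = classify_localization(omega)
    pole1_pct = 100.0 * pole1 / total
    pole2_pct = 100.0 * pole2 / total
    return CellQuantification(
        cell_label=cell.label,
        total_fluorescence=total,
        pole1_fluorescence=pole1,
        pole2_fluorescence=pole2,
        pole1_pct=pole1_pct,
        pole2_pct=pole2_pct,
        cytoplasmic_pct=100.0 - pole1_pct - pole2_pct,
        omega=omega,
        category=category,
        pole1_cap=pole1_cap,
        n_clusters=len(clusters),
    )


_CSV_COLUMNS = ["cell_label", "total", "pole1_pct", "pole2_pct",
                "cytoplasmic_pct", "omega", "category"]


def quantify_image(image: np.ndarray, mask: np.ndarray,
                   cap_extent: float = 1.0 / 6.0, k_sd: float = 2.0,
                   min_size: int = 3, subtract_cytoplasm: bool = False,
                   background: float | None = None,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Quantify every cell in a mask/image pair.

    Returns a table with one row per successfully quantified cell (fixed
    column order: cell_label, total, pole1_pct, pole2_pct, cytoplasmic_pct,
    omega, category) and a list of diagnostics for excluded cells.  The
    background defaults to the median of the non-cell pixels.
    """
    if background is None:
        background = estimate_background(image, mask)
    pairs, skipped = analyze_mask(mask, cap_extent=cap_extent)
    rows = []
    for cell, caps in pairs:
        try:
            q = quantify_cell(cell, image, caps, background=background,
                              k_sd=k_sd, min_size=min_size,
                              subtract_cytoplasm=subtract_cytoplasm)
        except QuantificationError as err:
            skipped.append(str(err))
            continue
        rows.append({
            "cell_label": q.cell_label,
            "total": q.total_fluorescence,
            "pole1_pct": q.pole1_pct,
            "pole2_pct": q.pole2_pct,
            "cytoplasmic_pct": q.cytoplasmic_pct,
            "omega": np.nan if q.omega is None else q.omega,
            "category": q.category.value,
        })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    return df, skipped
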