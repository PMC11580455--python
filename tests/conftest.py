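"""Shared fixtures: small synthetic scenes and independent oracles.

The oracle functions here deliberately avoid the code paths (and, where
feasible, the libraries) used by the implementation: cluster components are
enumerated with a hand-rolled flood fill over coordinate sets, and the
t statistic is computed from the textbook pooled-variance formula.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import polefrac as pf

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """25 bipolar-asymmetric cells (true fractions 0.35/0.15) with noise."""
    spec = pf.SceneSpec(n_cells=25, image_shape=(700, 700), seed=5)
    loc = pf.LocalizationSpec(pole1_fraction=0.35, pole2_fraction=0.15)
    mask, image, truth = pf.generate_scene(spec, loc)
    return mask, image, truth


@pytest.fixture(scope="session")
def noise_free_cell():
    """A single noise-free cell with fractions (0.4, 0.1)."""
    return make_single_cell(0.4, 0.1)


def make_single_cell(p1: float, p2: float, seed: int = 2):
    spec = pf.SceneSpec(n_cells=1, image_shape=(160, 160), seed=seed)
    loc = pf.LocalizationSpec(pole1_fraction=p1, pole2_fraction=p2,
                              shot_noise=False, read_noise_sd=0.0)
    mask, image, truth = pf.generate_scene(spec, loc)
    cell = pf.compute_axis(pf.extract_cells(mask)[0])
    caps = pf.define_polar_caps(cell)
    return mask, image, truth, cell, caps


# ---------------------------------------------------------------- oracles

def flood_fill_clusters(coords, values, thresh, min_size):
    """Brute-force polar-cluster oracle.

    Enumerates 8-connected components of the strictly suprathreshold pixels
    in ``coords``/``values`` via an explicit flood fill over a coordinate
    set, then applies the two detection rules (component size >= min_size,
    component mean >= thresh) independently of the pipeline's scipy-based
    labelling.  Returns a set of frozensets of (row, col).
    """
    candidate = {tuple(c): v for c, v in zip(coords, values) if v > thresh}
    seen: set[tuple[int, int]] = set()
    out = set()
    for start in candidate:
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            p = stack.pop()
            if p in seen or p not in candidate:
                continue
            seen.add(p)
            comp.append(p)
            r, c = p
            stack.extend((r + dr, c + dc)
                         for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                         if (dr, dc) != (0, 0))
        if len(comp) >= min_size and np.mean([candidate[p] for p in comp]) >= thresh:
            out.add(frozenset(comp))
    return out


def t_test_textbook(a, b):
    """Pooled-variance two-sample t-test from the textbook formula."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def random_cluster_cells(n_cells: int, seed: int):
    """Random 20 x 60 px rod cells with random spots/noise for oracle checks.

    Yields (cell, caps, image) triples; intensities are drawn so that some
    cells have bright polar spots, some dim ones, and some none at all.
    """
    rng = np.random.default_rng(seed)
    for i in range(n_cells):
        canvas = np.zeros((26, 66), dtype=np.int32)
        rr, cc = np.mgrid[0:26, 0:66]
        d = _seg_dist(rr, cc, np.array([12.5, 11.0]), np.array([12.5, 54.0]))
        canvas[d <= 9.0] = 1
        image = np.full(canvas.shape, 100.0)
        image += rng.normal(0.0, 8.0, size=canvas.shape)
        for anchor in ([12.5, 11.0], [12.5, 54.0]):
            if rng.random() < 0.7:
                amp = rng.uniform(5.0, 120.0)   # sometimes below threshold
                sigma = rng.uniform(1.0, 2.5)
                d2 = (rr - anchor[0]) ** 2 + (cc - anchor[1]) ** 2
                image += amp * np.exp(-d2 / (2 * sigma ** 2))
        cell = pf.compute_axis(pf.extract_cells(canvas, exclude_border=False)[0])
        caps = pf.define_polar_caps(cell)
        yield cell, caps, image


def _seg_dist(rr, cc, p0, p1):
    v = p1 - p0
    t = np.clip(((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / (v @ v), 0, 1)
    return np.hypot(rr - p0[0] - t * v[0], cc - p0[1] - t * v[1])
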