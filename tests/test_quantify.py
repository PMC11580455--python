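"""Polar cluster detection, omega, classification, per-cell quantification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import polefrac as pf
from polefrac.errors import (
    DegenerateDataError,
    QuantificationError,
    ValidationError,
)
from polefrac.quantify import Category

from conftest import flood_fill_clusters, make_single_cell, random_cluster_cells


def uniform_cell(height=9, width=48, inside=200.0, bg=100.0):
    mask = np.zeros((height + 6, width + 6), dtype=np.int32)
    mask[3:3 + height, 3:3 + width] = 1
    image = np.full(mask.shape, bg)
    image[mask == 1] = inside
    cell = pf.compute_axis(pf.extract_cells(mask)[0])
    return mask, image, cell, pf.define_polar_caps(cell)


class TestBackground:
    def test_constant_background(self):
        mask, image, *_ = uniform_cell()
        assert pf.estimate_background(image, mask) == 100.0

    def test_noisy_background_median_close(self):
        rng = np.random.default_rng(0)
        image = 100.0 + rng.normal(0, 5, size=(120, 120))  # >10^4 bg pixels
        mask = np.zeros_like(image, dtype=np.int32)
        mask[50:60, 50:60] = 1
        assert abs(pf.estimate_background(image, mask) - 100.0) < 0.5

    def test_no_background_pixels_is_error(self):
        image = np.ones((5, 5))
        with pytest.raises(ValidationError):
            pf.estimate_background(image, np.ones((5, 5), dtype=np.int32))


class TestCytoplasmicStats:
    def test_uniform_cell(self):
        _, image, cell, caps = uniform_cell()
        mean, sd = pf.cytoplasmic_stats(cell, image, caps, background=100.0)
        assert mean == pytest.approx(100.0)
        assert sd == 0.0

    def test_population_sd_convention(self):
        # mid-cell values alternating 90/110 after subtraction: the population
        # SD (divisor n) is 10 whether the count is even or odd +/- epsilon
        _, image, cell, caps = uniform_cell()
        mid_idx = np.flatnonzero(caps.mid)
        vals = np.where(np.arange(mid_idx.size) % 2 == 0, 190.0, 210.0)
        image[cell.rows[mid_idx], cell.cols[mid_idx]] = vals
        mean, sd = pf.cytoplasmic_stats(cell, image, caps, background=100.0)
        assert mean == pytest.approx(100.0, abs=0.5)
        assert sd == pytest.approx(10.0, abs=0.5)

    def test_matches_generator_diffuse_level(self, noise_free_cell):
        _, image, truth, cell, caps = noise_free_cell
        row = truth.cells.iloc[0]
        expected = (row.total_intensity
                    * (1 - row.pole1_fraction - row.pole2_fraction) / row.n_pixels)
        mean, _ = pf.cytoplasmic_stats(cell, image, caps, background=100.0)
        assert mean == pytest.approx(expected, rel=0.02)


class TestDetectClusters:
    def test_uniform_cell_has_no_clusters(self):
        _, image, cell, caps = uniform_cell()
        assert pf.detect_polar_clusters(cell, image, caps, background=100.0) == []

    def test_two_pixel_spot_below_min_size(self):
        _, image, cell, caps = uniform_cell()
        rr, cc = cell.rows[caps.cap_a][:2], cell.cols[caps.cap_a][:2]
        image[rr, cc] = 10_000.0  # 2 bright pixels only: size < 3 -> rejected
        clusters = pf.detect_polar_clusters(cell, image, caps, background=100.0)
        assert clusters == []

    def test_three_pixel_spot_detected(self):
        _, image, cell, caps = uniform_cell()
        sel = np.flatnonzero(caps.cap_a)[:3]
        image[cell.rows[sel], cell.cols[sel]] = 10_000.0
        clusters = pf.detect_polar_clusters(cell, image, caps, background=100.0)
        assert len(clusters) == 1
        assert clusters[0].cap == "A" and clusters[0].n_pixels >= 3

    def test_matches_brute_force_oracle(self):
        """Pixel sets identical to the flood-fill oracle on random cells."""
        for cell, caps, image in random_cluster_cells(12, seed=3):
            mean, sd = pf.cytoplasmic_stats(cell, image, caps)
            thresh = mean + 2.0 * sd
            found = pf.detect_polar_clusters(cell, image, caps,
                                             cyt_stats=(mean, sd))
            got = {frozenset(zip(c.rows.tolist(), c.cols.tolist())) for c in found}
            expected = set()
            for sel in (caps.cap_a, caps.cap_b):
                coords = list(zip(cell.rows[sel].tolist(), cell.cols[sel].tolist()))
                vals = image[cell.rows[sel], cell.cols[sel]]
                expected |= flood_fill_clusters(coords, vals, thresh, 3)
            assert got == expected


class TestPoleAssignment:
    def _cluster(self, cap, total):
        return pf.PolarCluster(1, cap, np.zeros(3, int), np.zeros(3, int),
                               total, total / 3)

    def test_brighter_cap_is_pole1(self):
        p1, p2, cap = pf.assign_poles([self._cluster("A", 300.0),
                                       self._cluster("B", 100.0)])
        assert (p1, p2, cap) == (300.0, 100.0, "A")

    def test_single_cluster_in_cap_b(self):
        p1, p2, cap = pf.assign_poles([self._cluster("B", 150.0)])
        assert (p1, p2, cap) == (150.0, 0.0, "B")

    def test_exact_tie_breaks_to_cap_a(self):
        p1, p2, cap = pf.assign_poles([self._cluster("A", 200.0),
                                       self._cluster("B", 200.0)])
        assert (p1, p2, cap) == (200.0, 200.0, "A")

    def test_no_clusters(self):
        assert pf.assign_poles([]) == (0.0, 0.0, None)


class TestOmegaAndClassification:
    @pytest.mark.parametrize("p1, p2, expected", [
        (100.0, 0.0, 1.0),
        (50.0, 50.0, 0.0),
        (75.0, 25.0, 0.5),
    ])
    def test_omega_values(self, p1, p2, expected):
        assert pf.asymmetry_index(p1, p2) == pytest.approx(expected)

    def test_omega_requires_ordered_positive_poles(self):
        with pytest.raises(ValidationError):
            pf.asymmetry_index(10.0, 20.0)
        with pytest.raises(DegenerateDataError):
            pf.asymmetry_index(0.0, 0.0)

    @pytest.mark.parametrize("omega, expected", [
        (0.95, Category.UNIPOLAR),
        (0.91, Category.UNIPOLAR),
        (0.9, Category.BIPOLAR_ASYMMETRIC),   # boundary belongs to the middle bin
        (0.5, Category.BIPOLAR_ASYMMETRIC),
        (0.2, Category.BIPOLAR_ASYMMETRIC),   # boundary
        (0.19, Category.BIPOLAR_SYMMETRIC),
        (0.0, Category.BIPOLAR_SYMMETRIC),
        (None, Category.DIFFUSE),
    ])
    def test_binning(self, omega, expected):
        assert pf.classify_localization(omega) is expected

    def test_omega_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            pf.classify_localization(1.5)

    @given(p1=st.floats(1.0, 1e6), f1=st.floats(0.0, 1.0), f2=st.floats(0.0, 1.0))
    def test_omega_strictly_decreasing_in_pole2(self, p1, f1, f2):
        lo, hi = sorted((f1, f2))
        if hi - lo > 1e-9:
            assert pf.asymmetry_index(p1, lo * p1) > pf.asymmetry_index(p1, hi * p1)


class TestQuantifyCell:
    def test_diffuse_only_cell(self):
        _, image, cell, caps = uniform_cell()
        q = pf.quantify_cell(cell, image, caps, background=100.0)
        assert q.pole1_pct == 0.0 and q.pole2_pct == 0.0
        assert q.cytoplasmic_pct == 100.0
        assert q.category is Category.DIFFUSE and q.omega is None

    def test_known_fractions_give_expected_percentages(self, noise_free_cell):
        _, image, _, cell, caps = noise_free_cell  # true fractions (0.4, 0.1)
        q = pf.quantify_cell(cell, image, caps, background=100.0,
                             subtract_cytoplasm=True)
        assert q.pole1_pct == pytest.approx(40.0, abs=2.0)
        assert q.pole2_pct == pytest.approx(10.0, abs=2.0)
        assert q.omega == pytest.approx(0.6, abs=0.03)
        assert q.category is Category.BIPOLAR_ASYMMETRIC
        assert q.pole1_pct + q.pole2_pct + q.cytoplasmic_pct == pytest.approx(
            100.0, abs=1e-6)

    def test_negative_total_excluded(self):
        _, image, cell, caps = uniform_cell(inside=50.0, bg=100.0)
        with pytest.raises(QuantificationError):
            pf.quantify_cell(cell, image, caps, background=100.0)

    def test_conservation_and_partition(self, small_scene):
        mask, image, _ = small_scene
        cells, skipped = pf.quantify_image(image, mask)
        assert skipped == []
        total = cells.pole1_pct + cells.pole2_pct + cells.cytoplasmic_pct
        assert np.allclose(total, 100.0, atol=1e-6)
        assert cells.category.isin([c.value for c in Category]).all()
        assert (cells.pole1_pct >= cells.pole2_pct).all()

    def test_intensity_scale_invariance(self, small_scene):
        mask, image, _ = small_scene
        bg = pf.estimate_background(image, mask)
        scaled = bg + 7.3 * (image - bg)
        a, _ = pf.quantify_image(image, mask, background=bg)
        b, _ = pf.quantify_image(scaled, mask, background=bg)
        assert (a.category == b.category).all()
        for col in ("pole1_pct", "pole2_pct", "cytoplasmic_pct"):
            assert np.allclose(a[col], b[col], atol=1e-9)
        assert np.allclose(a.omega.fillna(-1), b.omega.fillna(-1), atol=1e-9)

    def test_unipolar_mean_recovery(self):
        """Cells with true pole1 fraction 0.4: mean recovered pole1_pct ~ 40."""
        spec = pf.SceneSpec(n_cells=60, image_shape=(1100, 1100), seed=9)
        loc = pf.LocalizationSpec(pole1_fraction=0.4, pole2_fraction=0.0)
        mask, image, _ = pf.generate_scene(spec, loc)
        cells, _ = pf.quantify_image(image, mask)
        assert cells.pole1_pct.mean() == pytest.approx(40.0, abs=5.0)
        assert (cells.category == "unipolar").mean() > 0.9

    def test_noise_free_truth_category_recovery(self):
        """Noise-free scenes: pipeline category equals generator truth."""
        for p1, p2 in [(0.5, 0.0), (0.35, 0.15), (0.2, 0.2), (0.0, 0.0)]:
            spec = pf.SceneSpec(n_cells=12, image_shape=(520, 520), seed=13)
            loc = pf.LocalizationSpec(pole1_fraction=p1, pole2_fraction=p2,
                                      shot_noise=False, read_noise_sd=0.0)
            mask, image, truth = pf.generate_scene(spec, loc)
            cells, _ = pf.quantify_image(image, mask)
            merged = cells.merge(truth.cells, on="cell_label")
            assert (merged.category == merged.category_true).all()
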