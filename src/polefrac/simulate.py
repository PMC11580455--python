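"""Ground-truthed synthetic rod-cell scenes and motility trajectories.

The quantification pipeline is validated against synthetic data whose
ground truth is known exactly.  :func:`generate_scene` renders fields of
non-overlapping spherocylindrical rod cells (default ~0.5 x 5-7 um at
0.06 um/pixel, typical of a 100x objective on an sCMOS camera) carrying a
diffuse cytoplasmic signal plus zero, one or two polar fluorescent spots of
configurable intensity fractions, on a uniform background with optional
Poisson shot noise and Gaussian read noise.  :func:`generate_tracks`
produces constant-speed trajectories with programmed 180-degree reversals
and optional positional noise.

Ground truth is exact by construction: each polar spot is a Gaussian of
width ``cluster_sigma`` renormalized over its in-cell support, so the
integrated in-cell spot flux equals exactly ``fraction x total_intensity``
(no flux is lost to truncation at the cell boundary), and the noise-free
integrated cell signal equals ``total_intensity``.  The true localization
category is derived from the true pole fractions with the same asymmetry
index and binning used by the pipeline, so generator truth and pipeline
output are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .motility import Trajectory, trajectories_to_frame
from .quantify import asymmetry_index, classify_localization

__all__ = [
    "SceneSpec",
    "LocalizationSpec",
    "SceneTruth",
    "TrackSpec",
    "generate_scene",
    "generate_tracks",
    "write_scene",
    "write_tracks",
]


@dataclass
class SceneSpec:
    """Field-of-view and cell-shape parameters for a synthetic scene."""

    n_cells: int
    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.06
    cell_length_range_um: tuple[float, float] = (5.0, 7.0)
    cell_width_um: float = 0.5
    orientation: float | str = "random"   # radians, or "random"
    seed: int = 0
    max_attempts_per_cell: int = 200

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.pixel_size_um <= 0 or self.cell_width_um <= 0:
            raise ValidationError("pixel size and cell width must be positive")
        lo, hi = self.cell_length_range_um
        if not 0 < lo <= hi:
            raise ValidationError("cell_length_range_um must be positive and ordered")
        if lo <= self.cell_width_um:
            raise ValidationError("cells must be longer than they are wide")
        if isinstance(self.orientation, str) and self.orientation != "random":
            raise ValidationError("orientation must be 'random' or an angle in radians")


@dataclass
class LocalizationSpec:
    """Fluorescence allocation for one cell.

    ``pole1_fraction + pole2_fraction`` of ``total_intensity`` is placed in
    Gaussian polar spots (pole 1 >= pole 2 by convention); the remainder is
    spread uniformly over the cell (diffuse cytoplasmic signal).
    ``cluster_sigma_px`` defaults to a diffraction-limited spot width
    (~80 nm PSF sigma at 60 nm/pixel).
    """

    total_intensity: float = 50_000.0
    pole1_fraction: float = 0.0
    pole2_fraction: float = 0.0
    cluster_sigma_px: float = 1.3
    background_level: float = 100.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True

    def validate(self) -> None:
        if not 0 <= self.pole2_fraction <= self.pole1_fraction:
            raise ValidationError("need pole1_fraction >= pole2_fraction >= 0")
        if self.pole1_fraction + self.pole2_fraction > 1 + 1e-12:
            raise ValidationError("pole fractions must sum to <= 1")
        if self.total_intensity <= 0 or self.cluster_sigma_px <= 0:
            raise ValidationError("total_intensity and cluster_sigma_px must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValidationError("background and read noise must be non-negative")

    def true_category(self) -> str:
        if self.pole1_fraction == 0:
            return classify_localization(None).value
        omega = asymmetry_index(self.pole1_fraction, self.pole2_fraction)
        return classify_localization(omega).value


@dataclass
class SceneTruth:
    """Exact per-cell ground truth for a generated scene (one row per cell)."""

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _broadcast_locs(loc, n: int) -> list[LocalizationSpec]:
    if isinstance(loc, LocalizationSpec):
        locs = [loc] * n
    else:
        locs = list(loc)
        if len(locs) != n:
            raise ValidationError(
                f"expected {n} localization specs, got {len(locs)}"
            )
    for sp in locs:
        sp.validate()
    return locs


def generate_scene(spec: SceneSpec,
                   loc: LocalizationSpec | Sequence[LocalizationSpec],
                   ) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Generate a labelled mask, a fluorescence rendering, and its ground truth.

    Cells are placed by rejection sampling with a guaranteed >= 2-pixel gap
    between cells and a 2-pixel clear margin to the image border, so masks
    contain only separated, non-border cells.  Mask labels are consecutive
    integers 1..n_cells.  The returned fluorescence image is float64;
    quantisation to 16-bit happens only on disk (:func:`write_scene`).

    Raises :class:`PlacementError` (carrying the number of cells placed) if
    a cell cannot be placed within ``spec.max_attempts_per_cell`` attempts.
    """
    spec.validate()
    locs = _broadcast_locs(loc, spec.n_cells)
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.image_shape
    px = spec.pixel_size_um
    radius = spec.cell_width_um / 2.0 / px
    gap = 2.0
    margin = 2.0

    mask = np.zeros((nrows, ncols), dtype=np.int32)
    occupied = np.zeros((nrows, ncols), dtype=bool)
    placements = []  # (pixel rows, cols, segment endpoints p0/p1, tips)

    for i in range(spec.n_cells):
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            length_px = rng.uniform(*spec.cell_length_range_um) / px
            half_seg = length_px / 2.0 - radius
            theta = (rng.uniform(0, 2 * np.pi)
                     if spec.orientation == "random" else float(spec.orientation))
            u = np.array([np.sin(theta), np.cos(theta)])  # (row, col) direction
            bound = length_px / 2.0 + gap + margin + 1
            if nrows - 2 * bound <= 0 or ncols - 2 * bound <= 0:
                raise ValidationError("image too small for the requested cell size")
            center = rng.uniform([bound, bound], [nrows - bound, ncols - bound])
            p0, p1 = center - half_seg * u, center + half_seg * u

            r_lo = int(np.floor(min(p0[0], p1[0]) - radius - gap - 1))
            r_hi = int(np.ceil(max(p0[0], p1[0]) + radius + gap + 1)) + 1
            c_lo = int(np.floor(min(p0[1], p1[1]) - radius - gap - 1))
            c_hi = int(np.ceil(max(p0[1], p1[1]) + radius + gap + 1)) + 1
            rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            d = _dist_to_segment(rr, cc, p0, p1)
            inside = d <= radius
            dilated = d <= radius + gap
            if occupied[r_lo:r_hi, c_lo:c_hi][dilated].any():
                continue
            mask[r_lo:r_hi, c_lo:c_hi][inside] = i + 1
            occupied[r_lo:r_hi, c_lo:c_hi] |= dilated
            tips = np.array([p0 - radius * u, p1 + radius * u])
            placements.append((rr[inside] , cc[inside], p0, p1, tips))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1} after "
                f"{spec.max_attempts_per_cell} attempts", placed=i
            )

    fluor = np.zeros((nrows, ncols), dtype=np.float64)
    truth_rows = []
    for i, ((crows, ccols, p0, p1, tips), sp) in enumerate(zip(placements, locs)):
        label = i + 1
        n_px = crows.size
        diffuse_fraction = 1.0 - sp.pole1_fraction - sp.pole2_fraction
        fluor[crows, ccols] += sp.total_intensity * diffuse_fraction / n_px

        # randomize which physical pole carries the larger fraction
        if rng.random() < 0.5:
            anchors = (p0, p1)
        else:
            anchors = (p1, p0)
        spot_centers = [np.full(2, np.nan), np.full(2, np.nan)]
        for k, frac in enumerate((sp.pole1_fraction, sp.pole2_fraction)):
            if frac == 0:
                continue
            a = anchors[k]
            d2 = (crows - a[0]) ** 2 + (ccols - a[1]) ** 2
            w = np.exp(-d2 / (2.0 * sp.cluster_sigma_px ** 2))
            fluor[crows, ccols] += sp.total_intensity * frac * w / w.sum()
            spot_centers[k] = a
        truth_rows.append({
            "cell_label": label,
            "n_pixels": n_px,
            "total_intensity": sp.total_intensity,
            "pole1_fraction": sp.pole1_fraction,
            "pole2_fraction": sp.pole2_fraction,
            "omega_true": (np.nan if sp.pole1_fraction == 0
                           else asymmetry_index(sp.pole1_fraction, sp.pole2_fraction)),
            "category_true": sp.true_category(),
            "spot1_row": spot_centers[0][0], "spot1_col": spot_centers[0][1],
            "spot2_row": spot_centers[1][0], "spot2_col": spot_centers[1][1],
            "tipA_row": tips[0][0], "tipA_col": tips[0][1],
            "tipB_row": tips[1][0], "tipB_col": tips[1][1],
        })

    # camera model: expected counts -> shot noise -> additive read noise
    background = locs[0].background_level if locs else 100.0
    expected = fluor + background
    if locs and locs[0].shot_noise:
        image = rng.poisson(expected).astype(np.float64)
    else:
        image = expected
    read_sd = locs[0].read_noise_sd if locs else 0.0
    if read_sd > 0:
        image = image + rng.normal(0.0, read_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    truth = SceneTruth(cells=pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS))
    return mask, image, truth


_TRUTH_COLUMNS = [
    "cell_label", "n_pixels", "total_intensity", "pole1_fraction",
    "pole2_fraction", "omega_true", "category_true", "spot1_row", "spot1_col",
    "spot2_row", "spot2_col", "tipA_row", "tipA_col", "tipB_row", "tipB_col",
]


def _dist_to_segment(rr: np.ndarray, cc: np.ndarray,
                     p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from pixel centres (rr, cc) to the segment p0-p1."""
    v = p1 - p0
    vv = float(v @ v)
    dr, dc = rr - p0[0], cc - p0[1]
    if vv == 0:
        return np.hypot(dr, dc)
    t = np.clip((dr * v[0] + dc * v[1]) / vv, 0.0, 1.0)
    return np.hypot(dr - t * v[0], dc - t * v[1])


@dataclass
class TrackSpec:
    """Parameters for synthetic constant-speed trajectories with reversals.

    ``reversal_times_min`` may be a single list (applied to every track) or
    one list per track; times are minutes from the start, strictly
    increasing and inside the recording period.  ``frame_interval_s`` is
    20 s or 30 s in the standard assays but any positive divisor of the
    duration is accepted.
    """

    n_tracks: int
    speed_um_per_min: float = 2.0
    frame_interval_s: float = 30.0
    duration_min: float = 15.0
    reversal_times_min: Sequence[float] | Sequence[Sequence[float]] | None = None
    positional_noise_sd_um: float = 0.0
    seed: int = 0

    def per_track_reversals(self) -> list[list[float]]:
        rv = self.reversal_times_min
        if rv is None:
            per = [[] for _ in range(self.n_tracks)]
        elif len(rv) > 0 and isinstance(rv[0], (list, tuple, np.ndarray)):
            if len(rv) != self.n_tracks:
                raise ValidationError("need one reversal list per track")
            per = [list(map(float, r)) for r in rv]
        else:
            per = [list(map(float, rv)) for _ in range(self.n_tracks)]
        for times in per:
            arr = np.asarray(times, dtype=float)
            if arr.size and ((np.diff(arr) <= 0).any()
                             or arr[0] <= 0 or arr[-1] >= self.duration_min):
                raise ValidationError(
                    "reversal times must be strictly increasing and inside "
                    "(0, duration)"
                )
        return per

    def validate(self) -> None:
        if self.n_tracks < 0:
            raise ValidationError("n_tracks must be >= 0")
        if self.speed_um_per_min < 0 or self.positional_noise_sd_um < 0:
            raise ValidationError("speed and noise must be non-negative")
        if self.frame_interval_s <= 0 or self.duration_min <= 0:
            raise ValidationError("frame interval and duration must be positive")
        n_intervals = self.duration_min * 60.0 / self.frame_interval_s
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise ValidationError("duration must be a whole number of frame intervals")
        self.per_track_reversals()


def generate_tracks(spec: TrackSpec) -> tuple[list[Trajectory], pd.DataFrame]:
    """Generate trajectories plus a truth table of programmed reversal counts.

    Each track starts at a random position with a random heading, moves at
    constant speed, and flips its direction of motion by 180 degrees at each
    programmed reversal time (applied in continuous time, before sampling at
    the frame interval and before noise).  The truth table records the
    programmed reversal count and speed per track regardless of noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    per_track = spec.per_track_reversals()
    n_frames = int(round(spec.duration_min * 60.0 / spec.frame_interval_s)) + 1
    times_s = np.arange(n_frames) * spec.frame_interval_s
    v = spec.speed_um_per_min / 60.0  # um/s

    tracks, truth_rows = [], []
    for i, reversals in enumerate(per_track):
        origin = rng.uniform(0.0, 100.0, size=2)
        phi = rng.uniform(0.0, 2 * np.pi)
        u = np.array([np.cos(phi), np.sin(phi)])
        # signed time: direction sign flips at each reversal
        rev_s = np.asarray(reversals, dtype=float) * 60.0
        signed = np.empty(n_frames)
        for j, t in enumerate(times_s):
            n_flips_before = np.searchsorted(rev_s, t, side="right")
            # integrate sign over [0, t] across flip points
            bounds = np.concatenate([[0.0], rev_s[:n_flips_before], [t]])
            seg = np.diff(bounds)
            signs = (-1.0) ** np.arange(seg.size)
            signed[j] = float(signs @ seg)
        xy = origin + v * signed[:, None] * u
        if spec.positional_noise_sd_um > 0:
            xy = xy + rng.normal(0.0, spec.positional_noise_sd_um, size=xy.shape)
        tracks.append(Trajectory(cell_id=i + 1, times_s=times_s, xy_um=xy))
        truth_rows.append({
            "cell": i + 1,
            "n_reversals_true": len(reversals),
            "speed_um_per_min_true": spec.speed_um_per_min,
        })
    truth = pd.DataFrame(truth_rows, columns=["cell", "n_reversals_true",
                                              "speed_um_per_min_true"])
    return tracks, truth


def write_scene(out_dir: str | Path, mask: np.ndarray, image: np.ndarray,
                truth: SceneTruth) -> dict[str, Path]:
    """Write mask (16-bit TIFF), fluorescence (16-bit TIFF) and truth CSV."""
    from .io import write_image, write_labeled_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": out_dir / "mask.tif",
        "image": out_dir / "fluorescence.tif",
        "truth": out_dir / "truth.csv",
    }
    write_labeled_mask(paths["mask"], mask)
    write_image(paths["image"], image)
    truth.cells.to_csv(paths["truth"], index=False)
    return paths


def write_tracks(out_dir: str | Path, tracks: list[Trajectory],
                 truth: pd.DataFrame) -> dict[str, Path]:
    """Write trajectories and their truth table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"tracks": out_dir / "tracks.csv", "truth": out_dir / "track_truth.csv"}
    trajectories_to_frame(tracks).to_csv(paths["tracks"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
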