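"""Per-cell rod geometry: medial axis, pole tips, and polar caps.

The quantification of polar fluorescence needs a coordinate along the long
axis of each segmented rod cell.  This module derives, for every labelled
cell in a mask, an ordered medial-axis polyline running pole tip to pole
tip, an arc-length coordinate for every cell pixel (distance along the axis
from tip A), and the two "polar cap" pixel sets within which fluorescent
clusters count as polar.

The medial axis is obtained by skeletonising the cell, taking the longest
geodesic path through the skeleton (which prunes side branches), and
extending both ends along their local tangent until they leave the cell, so
that the axis reaches the actual pole tips rather than stopping half a cell
width short as raw skeletons do.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
8-connectivity is used throughout.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, ValidationError
from .io import read_labeled_mask  # re-exported: mask reading is part of this surface

__all__ = [
    "CellRegion",
    "PolarCaps",
    "read_labeled_mask",
    "extract_cells",
    "compute_axis",
    "define_polar_caps",
    "analyze_mask",
    "geometry_table",
]

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class CellRegion:
    """One segmented cell and (after :func:`compute_axis`) its rod geometry.

    Attributes
    ----------
    label : int
        Positive mask label.
    rows, cols : ndarray of int
        Pixel coordinates of the cell, parallel arrays.
    medial_axis : ndarray, shape (m, 2) or None
        Ordered polyline from pole tip A to pole tip B, in (row, col).
    pole_tips : ndarray, shape (2, 2) or None
        The two axis endpoints (tip A first).
    arc_coordinate : ndarray or None
        Per-pixel distance along the axis from tip A, in pixels.
    axis_length : float
        Total arc length of the medial axis, in pixels.
    width : float
        Estimated cell width (twice the mean distance from the skeleton to
        the cell boundary), in pixels.
    """

    label: int
    rows: np.ndarray
    cols: np.ndarray
    medial_axis: np.ndarray | None = None
    pole_tips: np.ndarray | None = None
    arc_coordinate: np.ndarray | None = None
    axis_length: float = float("nan")
    width: float = float("nan")
    touches_border: bool = False

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    @property
    def has_axis(self) -> bool:
        return self.medial_axis is not None

    def local_mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean raster over the cell's bounding box and its (row, col) offset."""
        r0, c0 = self.rows.min(), self.cols.min()
        out = np.zeros((self.rows.max() - r0 + 1, self.cols.max() - c0 + 1), bool)
        out[self.rows - r0, self.cols - c0] = True
        return out, (int(r0), int(c0))


@dataclass
class PolarCaps:
    """Partition of a cell's pixels into cap A, cap B, and mid-cell.

    Caps are defined by the arc coordinate: cap A is ``arc <= cap_extent * L``
    and cap B is ``arc >= (1 - cap_extent) * L`` where ``L`` is the axis
    length.  Boolean arrays are parallel to the cell's pixel arrays.
    """

    cap_extent: float
    cap_a: np.ndarray = field(repr=False)
    cap_b: np.ndarray = field(repr=False)

    @property
    def mid(self) -> np.ndarray:
        return ~(self.cap_a | self.cap_b)


def extract_cells(mask: np.ndarray, exclude_border: bool = True) -> list[CellRegion]:
    """Split a labelled mask into :class:`CellRegion` objects.

    One region per nonzero label.  Labels whose pixels form more than one
    8-connected component are rejected with a warning (they indicate a
    broken segmentation).  Cells touching the image border are flagged and,
    by default, excluded, because their truncated fluorescence would bias
    the polar fractions.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    nrows, ncols = mask.shape
    cells: list[CellRegion] = []
    objects = ndimage.find_objects(np.where(mask > 0, mask, 0))
    for i, sl in enumerate(objects):
        if sl is None:
            continue
        label = i + 1
        local = mask[sl] == label
        n_comp = ndimage.label(local, structure=_STRUCT8)[1]
        if n_comp > 1:
            warnings.warn(
                f"label {label} splits into {n_comp} 8-connected components; rejected",
                stacklevel=2,
            )
            continue
        rr, cc = np.nonzero(local)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        touches = bool(
            (rr == 0).any() or (rr == nrows - 1).any()
            or (cc == 0).any() or (cc == ncols - 1).any()
        )
        if touches and exclude_border:
            warnings.warn(f"label {label} touches the image border; excluded", stacklevel=2)
            continue
        cells.append(CellRegion(label=label, rows=rr, cols=cc, touches_border=touches))
    return cells


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Ordered (row, col) vertices of the longest geodesic path in a skeleton.

    Double-sweep Dijkstra with Euclidean step weights (1 or sqrt(2)); for the
    near-linear skeletons of rod cells this returns the backbone and prunes
    short side branches.
    """
    coords = np.argwhere(skel)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    n = len(coords)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append((j, float(np.hypot(dr, dc))))

    def dijkstra(src: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(n, np.inf)
        prev = np.full(n, -1, dtype=int)
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist[v]:
                    dist[v] = nd
                    prev[v] = u
                    heapq.heappush(heap, (nd, v))
        return dist, prev

    dist0, _ = dijkstra(0)
    u = int(np.argmax(np.where(np.isfinite(dist0), dist0, -1)))
    dist, prev = dijkstra(u)
    v = int(np.argmax(np.where(np.isfinite(dist), dist, -1)))
    path = [v]
    while prev[path[-1]] != -1:
        path.append(int(prev[path[-1]]))
    return coords[path[::-1]].astype(float)


def _extend_to_boundary(path: np.ndarray, local: np.ndarray, max_reach: float) -> np.ndarray:
    """Extend both ends of the axis polyline along their tangents to the cell edge."""
    from_end = min(4, len(path) - 1)
    out = [path]
    for end, other in ((path[0], path[min(from_end, len(path) - 1)]),
                       (path[-1], path[max(-1 - from_end, -len(path))])):
        t = end - other
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        tip = None
        for s in np.arange(0.25, max_reach, 0.25):
            pos = end + s * t
            r, c = int(round(pos[0])), int(round(pos[1]))
            if 0 <= r < local.shape[0] and 0 <= c < local.shape[1] and local[r, c]:
                tip = pos
            else:
                break
        if tip is not None:
            if np.array_equal(end, path[0]):
                out.insert(0, tip[None, :])
            else:
                out.append(tip[None, :])
    return np.vstack(out)


def compute_axis(cell: CellRegion, min_pixels: int = 9,
                 min_aspect: float = 2.0) -> CellRegion:
    """Compute the medial axis, pole tips and per-pixel arc coordinate.

    The pole tips are the two endpoints of the longest skeleton path after
    tangent extension to the cell boundary; every cell pixel is assigned the
    arc coordinate of its nearest axis vertex.  Cells that are too small
    (< ``min_pixels``) or too round (axis length < ``min_aspect`` x width)
    raise :class:`GeometryError` and should be excluded by the caller.
    """
    if cell.n_pixels < min_pixels:
        raise GeometryError(
            f"cell {cell.label}: {cell.n_pixels} pixels < {min_pixels}", label=cell.label
        )
    raw, (r0, c0) = cell.local_mask()
    local = np.pad(raw, 1)  # 1-px background rim so the EDT sees the boundary
    from skimage.morphology import skeletonize

    skel = skeletonize(local)
    if skel.sum() < 2:
        raise GeometryError(f"cell {cell.label}: degenerate skeleton", label=cell.label)
    path = _skeleton_longest_path(skel)

    edt = ndimage.distance_transform_edt(local)
    width = 2.0 * float(edt[path[:, 0].astype(int), path[:, 1].astype(int)].mean())

    # thinning leaves short diagonal branches ("hooks") where the skeleton
    # meets the rounded ends; trim half a width from each end so the tangent
    # extension follows the cell axis, not the hook
    trim = int(round(width / 2.0))
    if len(path) > 2 * trim + 4:
        path = path[trim:len(path) - trim]
    path = _extend_to_boundary(path, local, max_reach=width + trim + 2.0)
    path = path + np.array([r0 - 1, c0 - 1], dtype=float)

    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc_vertices = np.concatenate([[0.0], np.cumsum(seg)])
    axis_length = float(arc_vertices[-1])
    if axis_length < min_aspect * width:
        raise GeometryError(
            f"cell {cell.label}: axis length {axis_length:.1f} px < "
            f"{min_aspect} x width {width:.1f} px (cell too round)",
            label=cell.label,
        )

    pixels = np.column_stack([cell.rows, cell.cols]).astype(float)
    _, nearest = cKDTree(path).query(pixels)
    arc = arc_vertices[nearest]

    return CellRegion(
        label=cell.label,
        rows=cell.rows,
        cols=cell.cols,
        medial_axis=path,
        pole_tips=np.array([path[0], path[-1]]),
        arc_coordinate=arc,
        axis_length=axis_length,
        width=width,
        touches_border=cell.touches_border,
    )


def define_polar_caps(cell: CellRegion, cap_extent: float = 1.0 / 6.0) -> PolarCaps:
    """Partition a cell into two polar caps and a mid-cell region.

    ``cap_extent`` is the fraction of the axis length assigned to each cap;
    the default 1/6 approximates the hemispherical pole caps of a rod about
    six times longer than wide.  ``cap_extent`` = 0 gives empty caps;
    values >= 0.5 would make the caps overlap and are rejected.
    """
    if not cell.has_axis:
        raise ValidationError("define_polar_caps requires a computed axis")
    if cap_extent < 0 or cap_extent >= 0.5:
        raise ValidationError(f"cap_extent must be in [0, 0.5), got {cap_extent}")
    arc = cell.arc_coordinate
    if cap_extent == 0:
        empty = np.zeros(arc.size, bool)
        return PolarCaps(cap_extent=0.0, cap_a=empty, cap_b=empty.copy())
    lim = cap_extent * cell.axis_length
    cap_a = arc <= lim
    cap_b = arc >= cell.axis_length - lim
    # guard against numerically coincident caps on pathological short cells
    cap_b = cap_b & ~cap_a
    return PolarCaps(cap_extent=float(cap_extent), cap_a=cap_a, cap_b=cap_b)


def analyze_mask(mask: np.ndarray, cap_extent: float = 1.0 / 6.0,
                 exclude_border: bool = True
                 ) -> tuple[list[tuple[CellRegion, PolarCaps]], list[str]]:
    """Extract all cells from a mask with full geometry.

    Returns the list of (cell, caps) pairs for cells with a valid rod axis,
    plus a list of diagnostics for cells that were excluded.
    """
    out: list[tuple[CellRegion, PolarCaps]] = []
    skipped: list[str] = []
    for cell in extract_cells(mask, exclude_border=exclude_border):
        try:
            cell = compute_axis(cell)
        except GeometryError as err:
            skipped.append(str(err))
            continue
        out.append((cell, define_polar_caps(cell, cap_extent)))
    return out, skipped


def geometry_table(cells: list[CellRegion]) -> pd.DataFrame:
    """Per-cell geometry summary (label, size, axis length, tips) as a table."""
    rows = []
    for c in cells:
        tips = c.pole_tips if c.pole_tips is not None else np.full((2, 2), np.nan)
        rows.append({
            "cell_label": c.label,
            "n_pixels": c.n_pixels,
            "axis_length_px": c.axis_length,
            "width_px": c.width,
            "tipA_row": tips[0, 0], "tipA_col": tips[0, 1],
            "tipB_row": tips[1, 0], "tipB_col": tips[1, 1],
        })
    return pd.DataFrame(rows)
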