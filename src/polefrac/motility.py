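"""Single-cell motility metrics: per-interval speeds and reversal counts.

Rod-shaped surface-motile bacteria translocate along their long axis and
occasionally reverse direction.  Experimentally, cells are imaged for a
fixed recording period (15 min by default) at a constant frame interval
(20 s for pilus-dependent motility on polystyrene, 30 s for gliding on
agar), individual cells are tracked, and two metrics are computed per cell:
the speed per frame interval and the number of reversals per recording
window.  Only cells that moved for the entire recording period are
included; this is operationalized as "every interval displacement at least
``min_step``", the only frame-local deterministic reading.

A reversal is counted when the direction of net displacement (over steps of
at least ``min_step``) turns by more than ``angle_threshold`` (default
120 degrees) and the new direction persists for at least two intervals.
The persistence requirement makes the count robust to positional noise
while still detecting true 180-degree flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Trajectory",
    "TrackSummary",
    "interval_speeds",
    "count_reversals",
    "filter_moving",
    "summarize_motility",
    "trajectories_to_frame",
    "frame_to_trajectories",
]

#: default minimum per-interval displacement regarded as movement, in um
#: (half of the default 0.06 um camera pixel).
DEFAULT_MIN_STEP_UM = 0.03


@dataclass
class Trajectory:
    """Positions of one tracked cell: times in seconds, x/y in micrometres."""

    cell_id: int | str
    times_s: np.ndarray
    xy_um: np.ndarray  # shape (n_frames, 2)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.times_s.ndim != 1 or self.xy_um.shape != (self.times_s.size, 2):
            raise ValidationError("trajectory needs times (n,) and positions (n, 2)")
        if self.times_s.size < 2:
            raise ValidationError("trajectory needs at least 2 frames")
        dt = np.diff(self.times_s)
        if (dt <= 0).any():
            raise ValidationError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("frame interval must be constant")

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive frames, um, shape (n-1, 2)."""
        return np.diff(self.xy_um, axis=0)


@dataclass
class TrackSummary:
    cell_id: int | str
    speeds_um_per_min: np.ndarray = field(repr=False)
    mean_speed_um_per_min: float = 0.0
    n_reversals: int = 0
    reversals_per_window: float = 0.0
    moved_throughout: bool = False


def interval_speeds(traj: Trajectory, interval_s: float) -> np.ndarray:
    """Per-interval speeds in um/min.

    ``interval_s`` must match the trajectory's frame interval (20 s and 30 s
    are the standard recording settings); a mismatch indicates the wrong
    assay configuration and raises a validation error.
    """
    if not np.isclose(traj.frame_interval_s, interval_s, rtol=1e-6):
        raise ValidationError(
            f"trajectory interval {traj.frame_interval_s} s does not match "
            f"requested {interval_s} s"
        )
    disp = np.linalg.norm(traj.steps(), axis=1)
    return disp / interval_s * 60.0


def count_reversals(traj: Trajectory, angle_threshold_deg: float = 120.0,
                    min_step_um: float = DEFAULT_MIN_STEP_UM,
                    persistence: int = 2) -> int:
    """Count direction reversals along a trajectory.

    Steps shorter than ``min_step_um`` are ignored when establishing the
    direction of net displacement.  A reversal is counted when the direction
    turns by more than ``angle_threshold_deg`` relative to the current
    heading and the turned direction persists for ``persistence`` intervals
    (a flip on the final step, where no further interval exists to confirm
    persistence, is accepted).
    """
    if not 0 < angle_threshold_deg <= 180:
        raise ValidationError("angle_threshold_deg must be in (0, 180]")
    steps = traj.steps()
    norms = np.linalg.norm(steps, axis=1)
    keep = norms >= min_step_um
    dirs = steps[keep] / norms[keep, None]
    if len(dirs) < 2:
        return 0
    cos_thresh = np.cos(np.radians(angle_threshold_deg))

    def turned(d: np.ndarray, heading: np.ndarray) -> bool:
        return float(d @ heading) < cos_thresh

    heading = dirs[0]
    count = 0
    i = 1
    while i < len(dirs):
        if turned(dirs[i], heading):
            window = dirs[i:i + persistence]
            if all(turned(d, heading) for d in window):
                count += 1
                heading = window[-1]
                i += len(window)
                continue
        heading = dirs[i]
        i += 1
    return count


def filter_moving(tracks: list[Trajectory],
                  min_step_um: float = DEFAULT_MIN_STEP_UM) -> list[Trajectory]:
    """Keep only cells that moved for the entire recording period.

    A cell qualifies when every single interval displacement is at least
    ``min_step_um``; a cell that pauses for even one frame is excluded.
    """
    out = []
    for traj in tracks:
        disp = np.linalg.norm(traj.steps(), axis=1)
        if (disp >= min_step_um).all():
            out.append(traj)
    return out


def summarize_track(traj: Trajectory, interval_s: float | None = None,
                    window_min: float = 15.0,
                    angle_threshold_deg: float = 120.0,
                    min_step_um: float = DEFAULT_MIN_STEP_UM) -> TrackSummary:
    """Per-cell summary: mean speed, reversal count scaled to the window."""
    interval_s = traj.frame_interval_s if interval_s is None else interval_s
    speeds = interval_speeds(traj, interval_s)
    n_rev = count_reversals(traj, angle_threshold_deg, min_step_um)
    scale = (window_min * 60.0) / traj.duration_s
    moved = bool((np.linalg.norm(traj.steps(), axis=1) >= min_step_um).all())
    return TrackSummary(
        cell_id=traj.cell_id,
        speeds_um_per_min=speeds,
        mean_speed_um_per_min=float(speeds.mean()),
        n_reversals=n_rev,
        reversals_per_window=n_rev * scale,
        moved_throughout=moved,
    )


def summarize_motility(tracks: list[Trajectory], interval_s: float | None = None,
                       window_min: float = 15.0,
                       angle_threshold_deg: float = 120.0,
                       min_step_um: float = DEFAULT_MIN_STEP_UM,
                       apply_moving_filter: bool = True,
                       labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell motility table for a cohort of trajectories.

    Returns one row per included cell with the cell's mean speed (um/min)
    and reversals per ``window_min`` window.  Cells that did not move
    throughout the recording are dropped when ``apply_moving_filter`` is
    set.  ``labels`` may carry per-cell metadata (e.g. strain, replicate)
    indexed by ``cell`` and is merged into the output.
    """
    if apply_moving_filter:
        tracks = filter_moving(tracks, min_step_um)
    rows = []
    for traj in tracks:
        s = summarize_track(traj, interval_s, window_min,
                            angle_threshold_deg, min_step_um)
        rows.append({
            "cell": s.cell_id,
            "mean_speed_um_per_min": s.mean_speed_um_per_min,
            "n_reversals": s.n_reversals,
            "reversals_per_window": s.reversals_per_window,
            "moved_throughout": s.moved_throughout,
        })
    df = pd.DataFrame(rows, columns=["cell", "mean_speed_um_per_min", "n_reversals",
                                     "reversals_per_window", "moved_throughout"])
    if labels is not None and not df.empty:
        df = df.merge(labels, on="cell", how="left")
    return df


def trajectories_to_frame(tracks: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a tidy table (cell, time_s, x_um, y_um)."""
    frames = [
        pd.DataFrame({
            "cell": traj.cell_id,
            "time_s": traj.times_s,
            "x_um": traj.xy_um[:, 0],
            "y_um": traj.xy_um[:, 1],
        })
        for traj in tracks
    ]
    if not frames:
        return pd.DataFrame(columns=["cell", "time_s", "x_um", "y_um"])
    return pd.concat(frames, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for cell, grp in df.groupby("cell", sort=True):
        grp = grp.sort_values("time_s")
        out.append(Trajectory(cell_id=cell, times_s=grp["time_s"].to_numpy(),
                              xy_um=grp[["x_um", "y_um"]].to_numpy()))
    return out
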