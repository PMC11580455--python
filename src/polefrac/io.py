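"""Raster and table input/output.

Conventions used throughout the package:

* rasters are indexed ``(row, col)``, 0-based, origin at the top-left;
* labelled masks are integer rasters with 0 = background and positive
  integers identifying cells (labels need not be consecutive);
* fluorescence images are single-channel; on disk they are 16-bit TIFF,
  in memory they may be any real dtype (the synthetic generator returns
  float64 so that noise-free renderings are exact);
* trajectories are tables with columns ``cell``, ``time_s``, ``x_um``,
  ``y_um``, one row per cell per frame.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "read_labeled_mask",
    "write_labeled_mask",
    "read_image",
    "write_image",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "write_manifest",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def read_labeled_mask(path: str | Path) -> np.ndarray:
    """Read a labelled cell mask from TIFF or PNG.

    Labels are preserved exactly; 0 is background.  A non-integer raster is a
    format error; an all-zero mask is returned with a warning.
    """
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise FormatError(f"mask must be a single-channel 2-D raster, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"mask must be an integer raster, got dtype {arr.dtype}")
    if not arr.any():
        warnings.warn(f"mask {path} contains no cells (all background)", stacklevel=2)
    return arr.astype(np.int32, copy=False)


def write_labeled_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a labelled mask as 16-bit TIFF (PNG also supported by suffix)."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise FormatError("mask labels must fit in uint16 for on-disk storage")
    _write_raster(Path(path), mask.astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel fluorescence image as float64."""
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise FormatError(f"image must be single-channel 2-D, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a fluorescence image as 16-bit TIFF.

    Float images are rounded and clipped to the uint16 range; this
    quantisation is the only lossy step between the simulator's float64
    rendering and the on-disk format.
    """
    image = np.asarray(image, dtype=np.float64)
    clipped = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max)
    _write_raster(Path(path), clipped.astype(np.uint16))


def _write_raster(path: Path, arr: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_trajectories_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table (``cell``, ``time_s``, ``x_um``, ``y_um``)."""
    df = pd.read_csv(path)
    required = {"cell", "time_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trajectory table missing columns: {sorted(missing)}")
    return df


def write_trajectories_csv(path: str | Path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seed: int | None,
                   inputs: dict[str, str | Path] | None = None) -> Path:
    """Write a run manifest (config echo, seed, input hashes, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "polefrac_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                   for name, p in (inputs or {}).items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
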