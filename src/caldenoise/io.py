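"""Reading and writing movies, masks, traces and reports.

Movies travel as multi-page grayscale TIFF.  On write, intensities in [0, 1]
are scaled linearly to the integer code range (16-bit by default) and the
scaling plus sampling rate are recorded as JSON in the TIFF description; on
read, that metadata (or the dtype range) maps codes back to [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .movie import Movie

__all__ = [
    "MovieFormatError",
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "write_traces",
    "read_traces",
]


class MovieFormatError(ValueError):
    """Unreadable or unsupported movie file."""


def write_movie(movie: Movie, path: str | Path, bit_depth: int = 16) -> None:
    """Write a movie as multi-page grayscale TIFF with scaling metadata."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    vmax = 2**bit_depth - 1
    codes = np.clip(np.round(np.clip(movie.data, 0.0, 1.0) * vmax), 0, vmax)
    codes = codes.astype(np.uint8 if bit_depth == 8 else np.uint16)
    meta = json.dumps({"data_min": 0.0, "data_max": 1.0, "rate_hz": movie.rate_hz})
    tifffile.imwrite(path, codes, description=meta, photometric="minisblack")


def read_movie(path: str | Path, rate_hz: float | None = None) -> Movie:
    """Read a single- or multi-page grayscale TIFF as a Movie in [0, 1].

    Integer data are divided by their dtype maximum (or the recorded data
    range); float data pass through.  The sampling rate comes from recorded
    metadata unless overridden (default 40 Hz).
    """
    path = Path(path)
    if not path.exists():
        raise MovieFormatError(f"{path}: file not found")
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise MovieFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise MovieFormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        data = arr.astype(np.float64) / scale
    else:
        data = arr.astype(np.float64)
    rate = rate_hz if rate_hz is not None else float(meta.get("rate_hz", 40.0))
    return Movie(data, rate)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary ROI mask as a single-page 8-bit TIFF (0 / 255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary ROI mask from TIFF/PNG (nonzero = inside)."""
    path = Path(path)
    if not path.exists():
        raise MovieFormatError(f"{path}: file not found")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread  # PNG fallback

        arr = imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_traces(
    traces: np.ndarray, rate_hz: float, path: str | Path, cell_ids=None
) -> None:
    """Long-format CSV of per-cell traces: frame_index, time_s, cell_id, value."""
    traces = np.atleast_2d(traces)
    n_cells, n_frames = traces.shape
    if cell_ids is None:
        cell_ids = list(range(n_cells))
    rows = []
    for c, cid in enumerate(cell_ids):
        for t in range(n_frames):
            rows.append(
                {
                    "frame_index": t,
                    "time_s": t / rate_hz,
                    "cell_id": cid,
                    "value": traces[c, t],
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_traces(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
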