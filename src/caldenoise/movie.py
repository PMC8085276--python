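"""Core containers for two-photon imaging movies.

A *frame* is a 2-D ``numpy`` array of normalized fluorescence intensities;
ground-truth frames live in ``[0, 1]``.  A :class:`Movie` is an ordered frame
sequence with a sampling rate, stored as a single ``(T, H, W)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Movie", "validate_frame"]

_MIN_DIM = 8


def validate_frame(frame: np.ndarray, *, unit_range: bool = False) -> np.ndarray:
    """Check that ``frame`` is a finite 2-D intensity grid.

    Parameters
    ----------
    frame:
        2-D array of intensities.
    unit_range:
        If true, additionally require all intensities in ``[0, 1]``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")
    if frame.shape[0] < _MIN_DIM or frame.shape[1] < _MIN_DIM:
        raise ValueError(f"frame dimensions must be >= {_MIN_DIM}, got {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    if unit_range and (frame.min() < 0.0 or frame.max() > 1.0):
        raise ValueError("frame intensities must lie in [0, 1]")
    return frame


@dataclass
class Movie:
    """Ordered sequence of equally sized frames with a sampling rate.

    Attributes
    ----------
    data:
        ``(T, H, W)`` float array, frame index first.
    rate_hz:
        Sampling rate in Hz (frames per second), > 0.
    """

    data: np.ndarray
    rate_hz: float = 40.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (T, H, W), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.data.shape[1] < _MIN_DIM or self.data.shape[2] < _MIN_DIM:
            raise ValueError(f"frame dimensions must be >= {_MIN_DIM}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite intensities")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.rate_hz

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def copy(self) -> "Movie":
        return Movie(self.data.copy(), self.rate_hz)
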