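"""Image- and signal-quality metrics for denoising evaluation.

Spatial quality uses the two standard full-reference metrics, PSNR and
single-scale SSIM (11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03).
Temporal quality works on ROI fluorescence traces: relative fluorescence
df/f = (f - f0)/f0 with the baseline f0 taken as the 25th percentile of the
trace (linear-interpolation percentile convention), and a transient SNR

    SNR = (Peak - mean(Baseline)) / SD(Baseline)

where Peak is the mean df/f over a peak-centered 75 ms window and Baseline is
the df/f over the 2 s window ending immediately before the peak window.  At
40 Hz those windows resolve to 3 and 80 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import Movie

__all__ = [
    "psnr",
    "ssim",
    "QualityReport",
    "movie_quality",
    "Trace",
    "TransientWindow",
    "extract_trace",
    "transient_snr",
    "find_peak",
    "DegenerateBaselineError",
]

#: Cap used to represent +inf PSNR (identical images); any MSE = 0 maps here.
PSNR_CAP_DB = float("inf")


class DegenerateBaselineError(ValueError):
    """Raised when a baseline is unusable (f0 <= 0 or zero baseline SD)."""


def _check_same_shape(reference: np.ndarray, test: np.ndarray) -> None:
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(range^2 / MSE)``.

    Identical images have zero MSE and return ``inf``.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_same_shape(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return 10.0 * np.log10(data_range**2 / mse)


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
    win_size: int = 11,
) -> float:
    """Single-scale structural similarity with a Gaussian-weighted window.

    Local means/variances/covariance are computed with an ``win_size`` x
    ``win_size`` Gaussian window (population weighting); the SSIM map is
    averaged over the region where the window fits entirely inside the image.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_same_shape(reference, test)
    if min(reference.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}x{win_size} SSIM window")
    radius = (win_size - 1) // 2
    k = _gaussian_kernel_1d(sigma, radius)

    def smooth(a: np.ndarray) -> np.ndarray:
        out = ndimage.correlate1d(a, k, axis=0, mode="nearest")
        out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
        return out[radius:-radius, radius:-radius]  # window fully inside

    mu_x = smooth(reference)
    mu_y = smooth(test)
    xx = smooth(reference * reference) - mu_x * mu_x
    yy = smooth(test * test) - mu_y * mu_y
    xy = smooth(reference * test) - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * xy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (xx + yy + c2)
    return float(np.mean(num / den))


@dataclass
class QualityReport:
    """Per-frame PSNR/SSIM of a movie plus summary statistics."""

    per_frame: pd.DataFrame  # columns: frame, psnr_db, ssim
    psnr_mean: float
    psnr_sd: float
    ssim_mean: float
    ssim_sd: float


def movie_quality(reference: Movie | np.ndarray, test: Movie) -> QualityReport:
    """PSNR/SSIM of every test frame against the (broadcastable) reference.

    ``reference`` may be a movie of equal length or a single frame (fixed
    FOV) broadcast over all test frames.  Mean +- SD use the sample SD
    (ddof=1; 0 for a single frame).
    """
    ref = reference.data if isinstance(reference, Movie) else np.asarray(reference)
    if ref.ndim == 2:
        ref = np.broadcast_to(ref, test.data.shape)
    if ref.shape != test.data.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape} vs test {test.data.shape}")
    rows = []
    for i in range(test.n_frames):
        rows.append(
            {
                "frame": i,
                "psnr_db": psnr(ref[i], test.data[i]),
                "ssim": ssim(ref[i], test.data[i]),
            }
        )
    df = pd.DataFrame(rows)
    ddof = 1 if len(df) > 1 else 0
    return QualityReport(
        per_frame=df,
        psnr_mean=float(df.psnr_db.mean()),
        psnr_sd=float(df.psnr_db.std(ddof=ddof)),
        ssim_mean=float(df.ssim.mean()),
        ssim_sd=float(df.ssim.std(ddof=ddof)),
    )


@dataclass
class Trace:
    """ROI fluorescence time series with its df/f normalization."""

    f: np.ndarray
    rate_hz: float
    f0: float
    dff: np.ndarray


def extract_trace(movie: Movie, roi_mask: np.ndarray) -> Trace:
    """ROI-mean fluorescence per frame and its df/f.

    ``f0`` is the 25th percentile of the trace (linear interpolation between
    order statistics); ``dff = (f - f0) / f0`` requires ``f0 > 0``.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != movie.frame_shape:
        raise ValueError("ROI mask shape must match the frame shape")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    f = movie.data[:, roi_mask].mean(axis=1)
    f0 = float(np.percentile(f, 25))
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline f0 = {f0} is not positive")
    return Trace(f=f, rate_hz=movie.rate_hz, f0=f0, dff=(f - f0) / f0)


@dataclass
class TransientWindow:
    """Peak/baseline window definition for the transient SNR.

    The peak window (default 75 ms) is centered on ``peak_index``; the
    baseline window (default 2 s) ends immediately before the peak window
    starts.  Seconds convert to frames via ``max(1, round(s * rate))``.
    """

    peak_index: int
    peak_window_s: float = 0.075
    baseline_window_s: float = 2.0

    def frames(self, rate_hz: float) -> tuple[int, int]:
        n_peak = max(1, int(round(self.peak_window_s * rate_hz)))
        n_base = max(1, int(round(self.baseline_window_s * rate_hz)))
        return n_peak, n_base


def transient_snr(trace: Trace, window: TransientWindow) -> float:
    """Transient SNR: (peak mean - baseline mean) / baseline sample SD."""
    n_peak, n_base = window.frames(trace.rate_hz)
    start_peak = window.peak_index - n_peak // 2
    end_peak = start_peak + n_peak
    start_base = start_peak - n_base
    if start_base < 0 or end_peak > len(trace.dff):
        raise ValueError("peak/baseline windows do not fit inside the trace")
    peak = float(trace.dff[start_peak:end_peak].mean())
    baseline = trace.dff[start_base:start_peak]
    sd = float(baseline.std(ddof=1)) if len(baseline) > 1 else 0.0
    if sd == 0.0:
        raise DegenerateBaselineError("baseline SD is zero")
    return (peak - float(baseline.mean())) / sd


def find_peak(trace: Trace, search: slice | None = None) -> int:
    """Index of the df/f maximum (helper for choosing ``peak_index``)."""
    dff = trace.dff if search is None else trace.dff[search]
    offset = 0 if search is None else (search.start or 0)
    return int(np.argmax(dff)) + offset
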