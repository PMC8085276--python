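"""Synthetic two-photon Ca2+ imaging movies and the Poisson+Gaussian noise model.

The generator renders soma-like Gaussian blobs on a flat background and drives
each cell with a baseline plus Ca2+ transients (exponential rise/decay,
Poisson-process onsets).  Measurement corruption follows the mixed noise model

    m = t + ns_p(t) + ns_g

where ``t`` is the ground truth, ``ns_p`` is signal-dependent shot (Poisson)
noise and ``ns_g`` is i.i.d. zero-mean Gaussian read noise.  Shot noise is
parameterized by a photon budget ``B`` (expected photon count at intensity 1)
and a dimensionless magnitude ``a``:

    ns_p(t) = a * (Poisson(B * t) / B - t)

so that ``a = 1`` is physical shot noise at budget ``B`` and ``a = 0`` is an
exact identity.  Corrupted frames are *not* clipped; use :func:`clip_frame`
for export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .movie import Movie, validate_frame

__all__ = [
    "NoiseParams",
    "SceneConfig",
    "MotionParams",
    "generate_ground_truth_movie",
    "corrupt",
    "corrupt_movie",
    "add_motion",
    "average_reference",
    "random_rigid_motion",
    "random_nonuniform_motion",
    "clip_frame",
]


@dataclass
class NoiseParams:
    """Parameters of the Poisson+Gaussian corruption model.

    poisson_magnitude:
        Dimensionless scale of the zero-mean shot-noise deviation; 0 disables it.
    photon_budget:
        Expected photon count at intensity 1.0; sets the shot-noise shape.
    gaussian_sd:
        Standard deviation of the additive Gaussian component, intensity units.
    """

    poisson_magnitude: float = 1.0
    photon_budget: float = 1000.0
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_magnitude < 0:
            raise ValueError("poisson_magnitude must be >= 0")
        if not self.photon_budget > 0:
            raise ValueError("photon_budget must be > 0")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass
class SceneConfig:
    """Layout and kinetics of the synthetic field of view.

    Cells are isotropic Gaussian-profile blobs (sigma = cell_radius_px / 2),
    truncated at 2 sigma; the truncation disc is also the cell's binary mask.
    Each cell's brightness over time is ``soma_brightness * (1 + sum of
    transients)`` on top of ``background_level``; transients have exponential
    rise (rise_tau_s) and decay (decay_tau_s) and Poisson-process onsets at
    event_rate_hz.  Activity is capped so that peak blob intensity never
    exceeds 1 (indicator saturation), keeping ground truth in [0, 1] without
    clipping.
    """

    n_cells: int = 10
    cell_radius_px: float = 5.0
    background_level: float = 0.1
    soma_brightness: float = 0.35
    event_rate_hz: float = 0.25
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.5
    amplitude_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not self.cell_radius_px > 0:
            raise ValueError("cell_radius_px must be > 0")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must lie in [0, 1)")
        if not 0.0 < self.soma_brightness <= 1.0:
            raise ValueError("soma_brightness must lie in (0, 1]")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if not (self.rise_tau_s > 0 and self.decay_tau_s > 0):
            raise ValueError("time constants must be > 0")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("amplitude_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class MotionParams:
    """Per-frame motion: rigid shifts or dense displacement fields.

    Exactly one of ``shifts`` (``(T, 2)`` array of (dy, dx) pixel shifts) or
    ``fields`` (``(T, H, W, 2)`` displacement fields, pull convention) must be
    given.  ``interpolation`` is 'bilinear' (order 1) or 'nearest' (order 0);
    out-of-frame regions are filled with ``fill_value``.
    """

    shifts: np.ndarray | None = None
    fields: np.ndarray | None = None
    interpolation: str = "bilinear"
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.shifts is None) == (self.fields is None):
            raise ValueError("exactly one of shifts or fields must be provided")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError("interpolation must be 'bilinear' or 'nearest'")

    @property
    def order(self) -> int:
        return 1 if self.interpolation == "bilinear" else 0


def _transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential Ca2+ transient kernel, normalized to unit peak."""
    k = (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau)
    k[t < 0] = 0.0
    peak = k.max()
    if peak > 0:
        k = k / peak
    return k


def _place_cells(
    rng: np.random.Generator, n_cells: int, height: int, width: int, radius: float
) -> np.ndarray:
    """Rejection-sample non-overlapping blob centers; returns (n, 2) (y, x)."""
    mask_r = radius  # sigma = radius/2, truncated at 2 sigma = radius
    min_sep = 2.0 * mask_r + 1.0
    margin = mask_r + 1.0
    if height - 2 * margin < 0 or width - 2 * margin < 0:
        raise ValueError("frame too small for the requested cell radius")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        y = rng.uniform(margin, height - margin)
        x = rng.uniform(margin, width - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells of radius "
                f"{radius} in a {height}x{width} frame"
            )
    return np.asarray(centers, dtype=float).reshape(n_cells, 2)


def generate_ground_truth_movie(
    scene: SceneConfig,
    n_frames: int,
    rate_hz: float = 40.0,
    height: int = 500,
    width: int = 500,
) -> tuple[Movie, np.ndarray, np.ndarray]:
    """Render a noiseless Ca2+ imaging movie.

    Returns
    -------
    movie:
        Noiseless :class:`Movie`, intensities in ``[0, 1]``.
    cell_masks:
        ``(n_cells, H, W)`` boolean masks (blob truncation discs).
    true_traces:
        ``(n_cells, n_frames)`` exact mask-mean intensity time courses of the
        rendered movie (background + profile-weighted cell brightness).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not rate_hz > 0:
        raise ValueError("rate_hz must be > 0")
    if height < 8 or width < 8:
        raise ValueError("height and width must be >= 8")

    rng = np.random.default_rng(scene.seed)
    bg = scene.background_level
    frames = np.full((n_frames, height, width), bg, dtype=np.float64)
    masks = np.zeros((scene.n_cells, height, width), dtype=bool)
    traces = np.full((scene.n_cells, n_frames), bg, dtype=np.float64)
    if scene.n_cells == 0:
        return Movie(frames, rate_hz), masks, traces

    sigma = scene.cell_radius_px / 2.0
    trunc = 2.0 * sigma
    centers = _place_cells(rng, scene.n_cells, height, width, scene.cell_radius_px)
    t = np.arange(n_frames) / rate_hz
    duration = n_frames / rate_hz
    # activity cap so that bg + soma * a <= 1 at the blob center
    a_max = (1.0 - bg) / scene.soma_brightness

    yy, xx = np.mgrid[0:height, 0:width]
    for i, (cy, cx) in enumerate(centers):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        profile = np.exp(-r2 / (2.0 * sigma**2))
        inside = r2 <= trunc**2
        profile[~inside] = 0.0
        masks[i] = inside

        activity = np.ones(n_frames)
        n_events = rng.poisson(scene.event_rate_hz * duration)
        onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
        amps = rng.uniform(*scene.amplitude_range, size=n_events)
        for onset, amp in zip(onsets, amps):
            activity += amp * _transient_kernel(t - onset, scene.rise_tau_s, scene.decay_tau_s)
        activity = np.minimum(activity, a_max)

        brightness = scene.soma_brightness * activity  # (T,)
        frames[:, inside] += profile[inside][None, :] * brightness[:, None]
        traces[i] = bg + brightness * profile[inside].mean()

    return Movie(frames, rate_hz), masks, traces


def corrupt(
    frame: np.ndarray,
    params: NoiseParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the Poisson+Gaussian measurement model to one ground-truth frame.

    Output is ``t + magnitude * (Poisson(B t)/B - t) + N(0, sd^2)`` per pixel,
    *not* clipped.  Reproducible via ``params.seed`` when ``rng`` is omitted.
    """
    frame = validate_frame(frame)
    if frame.min() < 0:
        raise ValueError("ground-truth intensities must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = np.array(frame, dtype=np.float64, copy=True)
    if params.poisson_magnitude > 0:
        b = params.photon_budget
        shot = rng.poisson(b * frame) / b - frame
        out += params.poisson_magnitude * shot
    if params.gaussian_sd > 0:
        out += rng.normal(0.0, params.gaussian_sd, size=frame.shape)
    return out


def corrupt_movie(
    movie: Movie,
    params: NoiseParams,
    gaussian_sd_range: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Movie, np.ndarray]:
    """Corrupt every frame; optionally draw a fresh Gaussian SD per frame.

    Returns the noisy movie and the ``(T,)`` array of Gaussian SDs used.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sds = np.empty(movie.n_frames)
    out = np.empty_like(movie.data, dtype=np.float64)
    for i in range(movie.n_frames):
        sd = params.gaussian_sd if gaussian_sd_range is None else rng.uniform(*gaussian_sd_range)
        sds[i] = sd
        p = NoiseParams(params.poisson_magnitude, params.photon_budget, sd, params.seed)
        out[i] = corrupt(movie.data[i], p, rng=rng)
    return Movie(out, movie.rate_hz), sds


def add_motion(movie: Movie, motion: MotionParams) -> Movie:
    """Warp each frame by its per-frame shift or displacement field."""
    T, H, W = movie.data.shape
    out = np.empty_like(movie.data, dtype=np.float64)
    if motion.shifts is not None:
        shifts = np.asarray(motion.shifts, dtype=float)
        if shifts.shape != (T, 2):
            raise ValueError(f"shifts must have shape ({T}, 2), got {shifts.shape}")
        for i in range(T):
            if shifts[i, 0] == 0.0 and shifts[i, 1] == 0.0:
                out[i] = movie.data[i]
            else:
                # pull convention: output(y,x) = input(y+dy, x+dx)
                out[i] = ndimage.shift(
                    movie.data[i],
                    -shifts[i],
                    order=motion.order,
                    mode="constant",
                    cval=motion.fill_value,
                )
    else:
        fields = np.asarray(motion.fields, dtype=float)
        if fields.shape != (T, H, W, 2):
            raise ValueError(f"fields must have shape ({T}, {H}, {W}, 2), got {fields.shape}")
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        for i in range(T):
            if not fields[i].any():
                out[i] = movie.data[i]
                continue
            coords = np.stack([yy + fields[i, :, :, 0], xx + fields[i, :, :, 1]])
            out[i] = ndimage.map_coordinates(
                movie.data[i],
                coords,
                order=motion.order,
                mode="constant",
                cval=motion.fill_value,
            )
    return Movie(out, movie.rate_hz)


def random_rigid_motion(
    n_frames: int, max_shift_px: float, seed: int = 0, fill_value: float = 0.0
) -> MotionParams:
    """Uniform random per-frame rigid shifts in ``[-max_shift, max_shift]``."""
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(-max_shift_px, max_shift_px, size=(n_frames, 2))
    return MotionParams(shifts=shifts, fill_value=fill_value, seed=seed)


def random_nonuniform_motion(
    n_frames: int,
    height: int,
    width: int,
    amplitude_px: float,
    grid: int = 4,
    seed: int = 0,
    fill_value: float = 0.0,
) -> MotionParams:
    """Smooth random displacement fields (coarse random grid, upsampled).

    Emulates motion-induced nonuniform deformations: each frame gets an
    independent ``(H, W, 2)`` field whose values vary smoothly across the FOV
    with RMS amplitude ~``amplitude_px``.
    """
    rng = np.random.default_rng(seed)
    fields = np.empty((n_frames, height, width, 2))
    for i in range(n_frames):
        coarse = rng.normal(0.0, amplitude_px, size=(grid, grid, 2))
        for c in range(2):
            fields[i, :, :, c] = ndimage.zoom(
                coarse[:, :, c], (height / grid, width / grid), order=3, mode="nearest"
            )
    return MotionParams(fields=fields, fill_value=fill_value, seed=seed)


def average_reference(frames: Sequence[np.ndarray] | Movie | np.ndarray) -> np.ndarray:
    """Pixel-wise mean of equally sized frames (reference construction).

    Averaging N independent noisy frames of a fixed FOV shrinks the noise by
    1/sqrt(N); the standard reference uses N = 100.
    """
    if isinstance(frames, Movie):
        stack = frames.data
    else:
        frames = list(frames) if not isinstance(frames, np.ndarray) else frames
        if len(frames) == 0:
            raise ValueError("cannot average an empty frame sequence")
        stack = np.stack([np.asarray(f) for f in frames])
    if stack.shape[0] == 0:
        raise ValueError("cannot average an empty frame sequence")
    if stack.ndim != 3:
        raise ValueError("frames must all be 2-D and equally sized")
    return stack.mean(axis=0)


def clip_frame(frame: np.ndarray) -> np.ndarray:
    """Clip intensities to [0, 1] (export utility; corruption never clips)."""
    return np.clip(frame, 0.0, 1.0)
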