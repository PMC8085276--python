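"""Training datasets for the two-stage denoising procedure.

Stage 1 (supervised): a clean reference frame is corrupted three times with
the Poisson+Gaussian model — one Gaussian SD drawn per sequence and shared by
its three frames — and the three noisy frames are stacked as the network
input; the target is the reference replicated into three channels
(full-scale: 1,200 pairs).

Stage 2 (noise-to-noise): a raw movie is partitioned into non-overlapping
windows of four consecutive frames; frames 1-3 form the input stack and
frame 4 (replicated three times) is the target (full-scale: 900 pairs).
No clean data enters this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .movie import Movie, validate_frame
from .simulate import NoiseParams, corrupt

__all__ = [
    "TrainingPair",
    "make_supervised_pairs",
    "make_n2n_pairs",
    "extract_patches",
    "split_pairs",
]

DEFAULT_SD_RANGE = (0.0, 0.05)


@dataclass
class TrainingPair:
    """One input/target stack pair.

    input_stack / target_stack are ``(H, W, 3)`` float32 arrays; all three
    target channels are identical.  ``stage_tag`` is 'supervised' or
    'noise2noise'; ``meta`` records provenance (source frame indices, the
    Gaussian SD used, crop offsets).
    """

    input_stack: np.ndarray
    target_stack: np.ndarray
    stage_tag: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_stack.shape != self.target_stack.shape:
            raise ValueError("input and target stacks must share a shape")
        if self.input_stack.ndim != 3 or self.input_stack.shape[-1] != 3:
            raise ValueError("stacks must be (H, W, 3)")
        if self.stage_tag not in ("supervised", "noise2noise"):
            raise ValueError(f"unknown stage_tag {self.stage_tag!r}")


def _replicate(frame: np.ndarray) -> np.ndarray:
    return np.repeat(frame[:, :, None], 3, axis=2).astype(np.float32)


def make_supervised_pairs(
    reference: np.ndarray,
    n_pairs: int,
    noise: NoiseParams,
    gaussian_sd_range: tuple[float, float] = DEFAULT_SD_RANGE,
    rng: np.random.Generator | None = None,
) -> list[TrainingPair]:
    """Noisy-stack -> clean-reference pairs for the supervised stage.

    For each pair one Gaussian SD is drawn uniformly from
    ``gaussian_sd_range`` and shared by the pair's three independently
    corrupted copies of ``reference``; the Poisson component comes from
    ``noise``.  Passing ``gaussian_sd_range=None`` semantics are not needed:
    use a degenerate range ``(sd, sd)`` for a fixed SD.
    """
    reference = validate_frame(reference, unit_range=True)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    target = _replicate(reference)
    pairs = []
    for k in range(n_pairs):
        sd = float(rng.uniform(*gaussian_sd_range))
        p = NoiseParams(noise.poisson_magnitude, noise.photon_budget, sd, noise.seed)
        stack = np.stack(
            [corrupt(reference, p, rng=rng) for _ in range(3)], axis=2
        ).astype(np.float32)
        pairs.append(
            TrainingPair(stack, target.copy(), "supervised", {"pair_id": k, "gaussian_sd": sd})
        )
    return pairs


def make_n2n_pairs(movie: Movie, max_pairs: int | None = None) -> list[TrainingPair]:
    """Noise-to-noise pairs from non-overlapping 4-frame windows of a movie.

    Window ``[4k, 4k+3]`` yields input = frames ``4k..4k+2`` stacked and
    target = frame ``4k+3`` replicated; at most ``min(T // 4, max_pairs)``
    pairs are produced.
    """
    if movie.n_frames < 4:
        raise ValueError("noise-to-noise pairing requires at least 4 frames")
    n = movie.n_frames // 4
    if max_pairs is not None:
        n = min(n, max_pairs)
    pairs = []
    for k in range(n):
        i = 4 * k
        stack = np.stack([movie.data[i], movie.data[i + 1], movie.data[i + 2]], axis=2)
        pairs.append(
            TrainingPair(
                stack.astype(np.float32),
                _replicate(movie.data[i + 3]),
                "noise2noise",
                {"pair_id": k, "source_frames": (i, i + 1, i + 2, i + 3)},
            )
        )
    return pairs


def extract_patches(
    pairs: Sequence[TrainingPair],
    patch_size: int,
    per_pair: int = 1,
    seed: int = 0,
) -> list[TrainingPair]:
    """Random aligned crops, applied identically to input and target."""
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        h, w, _ = pair.input_stack.shape
        if patch_size > h or patch_size > w:
            raise ValueError(f"patch_size {patch_size} exceeds frame size {h}x{w}")
        for _ in range(per_pair):
            y = int(rng.integers(0, h - patch_size + 1))
            x = int(rng.integers(0, w - patch_size + 1))
            sl = (slice(y, y + patch_size), slice(x, x + patch_size))
            meta = dict(pair.meta, crop=(y, x))
            out.append(
                TrainingPair(
                    pair.input_stack[sl].copy(),
                    pair.target_stack[sl].copy(),
                    pair.stage_tag,
                    meta,
                )
            )
    return out


def split_pairs(
    pairs: Sequence[TrainingPair], val_fraction: float = 0.1, seed: int = 0
) -> tuple[list[TrainingPair], list[TrainingPair]]:
    """Deterministic seeded train/validation split (default 90/10)."""
    if not pairs:
        raise ValueError("cannot split an empty dataset")
    idx = np.random.default_rng(seed).permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs)))) if len(pairs) > 1 else 0
    val_idx = set(idx[:n_val].tolist())
    train = [pairs[i] for i in range(len(pairs)) if i not in val_idx]
    val = [pairs[i] for i in range(len(pairs)) if i in val_idx]
    return train, val
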