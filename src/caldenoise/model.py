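"""The 20-layer residual spatiotemporal denoising network.

The network takes a stack of three consecutive frames (as three channels) and
estimates the *residual noise* of the stack: layer 1 maps 3 -> 128 channels,
layers 2..19 map to 64 channels, and layer 20 maps back to 3 channels with no
activation.  Every convolution is 3x3xC with same (zero) padding, followed by
a leaky ReLU except for the last layer; there is no normalization.  The clean
estimate of the middle frame is ``mean(stack - residual)`` over the three
output channels, clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._engine import Adam, conv2d, conv2d_backward, im2col, leaky_relu
from .movie import Movie

__all__ = [
    "ModelConfig",
    "Model",
    "build_model",
    "predict_residual",
    "denoise_stack",
    "denoise_movie",
    "save_checkpoint",
    "load_checkpoint",
]

# max pixels per inference batch; keeps im2col buffers ~100 MB
_PIXEL_BUDGET = 1 << 17


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults are the published network)."""

    depth: int = 20
    first_layer_filters: int = 128
    hidden_filters: int = 64
    kernel_size: int = 3
    channels_c: int = 3
    lrelu_slope: float = 0.1

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValueError("depth must be >= 3")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.channels_c != 3:
            raise ValueError("channels_c must equal the stack depth 3")
        if not 0.0 < self.lrelu_slope < 1.0:
            raise ValueError("lrelu_slope must lie in (0, 1)")

    @property
    def filter_plan(self) -> list[int]:
        """Output channel count of each layer."""
        return (
            [self.first_layer_filters]
            + [self.hidden_filters] * (self.depth - 2)
            + [self.channels_c]
        )


class Model:
    """Convolutional residual-noise estimator.

    ``weights`` is a list of ``(W, b)`` per layer with ``W`` flat as
    ``(k*k*c_in, c_out)`` float32.  ``provenance`` is one of 'untrained',
    'initial-trained', 'fine-tuned'.
    """

    def __init__(
        self,
        config: ModelConfig,
        weights: list[tuple[np.ndarray, np.ndarray]],
        provenance: str = "untrained",
        seed: int | None = None,
    ) -> None:
        self.config = config
        self.weights = weights
        self.provenance = provenance
        self.seed = seed

    # ------------------------------------------------------------------ shape
    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in self.weights)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[-1] != self.config.channels_c:
            raise ValueError(
                f"expected (N, H, W, {self.config.channels_c}) input, got {x.shape}"
            )
        k = self.config.kernel_size
        if x.shape[1] < k or x.shape[2] < k:
            raise ValueError("input smaller than the kernel")

    # -------------------------------------------------------------- inference
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Residual estimate for a batch of stacks; pure and deterministic."""
        self._check_input(x)
        k = self.config.kernel_size
        slope = self.config.lrelu_slope
        a = np.ascontiguousarray(x, dtype=np.float32)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(self.weights):
            a, _ = conv2d(a, w, b, k)
            if i != last:
                a = leaky_relu(a, slope)
        return a

    # --------------------------------------------------------------- training
    def forward_train(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Forward pass retaining per-layer caches for backprop."""
        self._check_input(x)
        k = self.config.kernel_size
        slope = self.config.lrelu_slope
        a = np.ascontiguousarray(x, dtype=np.float32)
        caches = []
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(self.weights):
            z, col = conv2d(a, w, b, k)
            caches.append((col, z if i != last else None))
            a = leaky_relu(z, slope) if i != last else z
        return a, caches

    def backward(self, caches: list, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. all parameters, flat [dW0, db0, dW1, db1, ...]."""
        k = self.config.kernel_size
        slope = self.config.lrelu_slope
        plan_in = [self.config.channels_c] + self.config.filter_plan[:-1]
        grads: list[np.ndarray] = []
        g = np.ascontiguousarray(grad_out, dtype=np.float32)
        for i in reversed(range(len(self.weights))):
            col, _ = caches[i]
            w, _b = self.weights[i]
            dx, dw, db = conv2d_backward(g, col, w, k, plan_in[i], need_dx=i > 0)
            grads.append(db)
            grads.append(dw)
            if i > 0:
                _, z_prev = caches[i - 1]
                g = dx * np.where(z_prev > 0, np.float32(1.0), np.float32(slope))
        grads.reverse()
        return grads

    @property
    def parameters(self) -> list[np.ndarray]:
        flat: list[np.ndarray] = []
        for w, b in self.weights:
            flat.append(w)
            flat.append(b)
        return flat

    def copy_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(w.copy(), b.copy()) for w, b in self.weights]

    def set_weights(self, weights: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.weights = [(w.copy(), b.copy()) for w, b in weights]


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Model:
    """Initialize an untrained network.

    Weights use fan-in variance scaling with the leaky-ReLU gain
    ``sqrt(2 / (1 + slope^2))``; biases start at zero.  Bit-reproducible for a
    fixed seed.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    k = config.kernel_size
    gain = np.sqrt(2.0 / (1.0 + config.lrelu_slope**2))
    weights = []
    c_in = config.channels_c
    for c_out in config.filter_plan:
        fan_in = k * k * c_in
        std = gain / np.sqrt(fan_in)
        w = rng.normal(0.0, std, size=(fan_in, c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        weights.append((w, b))
        c_in = c_out
    return Model(config, weights, provenance="untrained", seed=seed)


def predict_residual(model: Model, stack: np.ndarray) -> np.ndarray:
    """Residual-noise estimate for one ``(H, W, 3)`` stack (no clipping)."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[-1] != model.config.channels_c:
        raise ValueError(f"expected (H, W, 3) stack, got shape {stack.shape}")
    return model.forward(stack[None])[0]


def denoise_stack(model: Model, stack: np.ndarray) -> np.ndarray:
    """Clean middle-frame estimate from a 3-frame stack.

    Subtracts the predicted residual per channel, averages the three cleaned
    channels, and clips to [0, 1].
    """
    residual = predict_residual(model, stack)
    clean = np.asarray(stack, dtype=np.float64) - residual
    return np.clip(clean.mean(axis=-1), 0.0, 1.0)


def _movie_stacks(movie: Movie) -> np.ndarray:
    """(T, H, W, 3) sliding stacks with replicate padding at the ends."""
    d = movie.data
    prev = np.concatenate([d[:1], d[:-1]], axis=0)
    nxt = np.concatenate([d[1:], d[-1:]], axis=0)
    return np.stack([prev, d, nxt], axis=-1)


def denoise_movie(model: Model, movie: Movie) -> Movie:
    """Denoise every frame of a movie via its (n-1, n, n+1) stack.

    Edge frames use replicate padding of the frame sequence, so the output
    has exactly the input's frame count.  Frames are processed in batches but
    the network is stateless, so batching cannot change the result.
    """
    if movie.n_frames < 1:
        raise ValueError("movie must contain at least one frame")
    stacks = _movie_stacks(movie).astype(np.float32)
    h, w = movie.frame_shape
    batch = max(1, _PIXEL_BUDGET // (h * w))
    out = np.empty_like(movie.data, dtype=np.float64)
    for start in range(0, movie.n_frames, batch):
        chunk = stacks[start : start + batch]
        residual = model.forward(chunk)
        clean = chunk.astype(np.float64) - residual
        out[start : start + batch] = np.clip(clean.mean(axis=-1), 0.0, 1.0)
    return Movie(out, movie.rate_hz)


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(model: Model, path: str | Path) -> None:
    """Single-archive checkpoint: config + weights + provenance + seed."""
    path = Path(path)
    arrays = {}
    for i, (w, b) in enumerate(model.weights):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    header = json.dumps(
        {
            "config": asdict(model.config),
            "provenance": model.provenance,
            "seed": model.seed,
            "n_layers": len(model.weights),
        }
    )
    with open(path, "wb") as fh:  # exact path; avoid numpy's .npz suffixing
        np.savez(fh, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Model:
    """Load a checkpoint; inference is bit-identical to the saved model."""
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        config = ModelConfig(**header["config"])
        weights = [(z[f"w{i}"], z[f"b{i}"]) for i in range(header["n_layers"])]
    return Model(config, weights, provenance=header["provenance"], seed=header["seed"])
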