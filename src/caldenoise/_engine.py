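"""Minimal convolutional network engine (numpy + BLAS).

Implements same-padded 2-D convolution as im2col + GEMM, with hand-derived
backward passes, for the fixed feed-forward architectures this package uses.
All tensors are channels-last: activations ``(N, H, W, C)``, weights stored
flat as ``(k*k*C_in, C_out)`` with (ky, kx, c_in) row order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["im2col", "conv2d", "conv2d_backward", "leaky_relu", "Adam"]


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold ``(N, H, W, C)`` into ``(N*H*W, k*k*C)`` patch rows (zero pad)."""
    n, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    col = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    idx = 0
    for dy in range(k):
        for dx in range(k):
            col[:, :, :, idx, :] = xp[:, dy : dy + h, dx : dx + w, :]
            idx += 1
    return col.reshape(n * h * w, k * k * c)


def conv2d(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded convolution; returns (output, cached im2col of x)."""
    n, h, w, _ = x.shape
    col = im2col(x, k)
    y = col @ weight + bias
    return y.reshape(n, h, w, weight.shape[1]), col


def conv2d_backward(
    grad_y: np.ndarray,
    col_x: np.ndarray,
    weight: np.ndarray,
    k: int,
    c_in: int,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of a same-padded convolution.

    grad_y: ``(N, H, W, C_out)``; col_x: cached im2col of the forward input.
    Returns (dx, dW, db); dx is None when ``need_dx`` is false (first layer).
    """
    n, h, w, c_out = grad_y.shape
    gy = grad_y.reshape(-1, c_out)
    d_weight = col_x.T @ gy
    d_bias = gy.sum(axis=0)
    if not need_dx:
        return None, d_weight, d_bias
    # dx = conv(grad_y, weight rotated 180 deg with in/out channels swapped)
    w4 = weight.reshape(k, k, c_in, c_out)
    w_rot = w4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * c_out, c_in)
    col_g = im2col(grad_y, k)
    dx = (col_g @ w_rot).reshape(n, h, w, c_in)
    return dx, d_weight, d_bias


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


class Adam:
    """Adaptive moment estimation over a flat list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
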