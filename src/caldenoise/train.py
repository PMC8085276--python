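"""Two-stage training: supervised initial training, noise-to-noise fine-tuning.

The network learns the residual: for an input stack ``x`` and target stack
``y`` the desired residual is ``x - y`` and the loss is the mean squared
error between the predicted and desired residuals over all pixels and
channels (L2 residual loss).  Stage 1 trains from scratch on synthetic
noisy-input/clean-target pairs for 50 epochs (Adam, constant lr 1e-4);
stage 2 re-uses the trained weights and retrains the whole network — nothing
frozen — on raw 4-frame noise-to-noise pairs for 10 epochs.  Because stage-2
targets are themselves noisy, the stage-2 loss is floored near the target
noise variance and is expected to stay large.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._engine import Adam
from .data import TrainingPair, split_pairs
from .model import Model, save_checkpoint

__all__ = [
    "TrainConfig",
    "LossRecord",
    "residual_loss",
    "train_initial",
    "finetune",
    "evaluate_epoch",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the published settings)."""

    learning_rate: float = 1e-4
    epochs_initial: int = 50
    epochs_finetune: int = 10
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    val_fraction: float = 0.1
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LossRecord:
    """Per-epoch loss bookkeeping for one training stage."""

    stage: str
    epoch: int
    mean_training_loss: float
    mean_validation_loss: float

    def __post_init__(self) -> None:
        for v in (self.mean_training_loss, self.mean_validation_loss):
            if not np.isfinite(v) or v < 0:
                raise ValueError("losses must be finite and non-negative")


def residual_loss(
    predicted: np.ndarray, input_stack: np.ndarray, target_stack: np.ndarray
) -> float:
    """Mean squared error between predicted and desired (input-target) residuals."""
    if not (predicted.shape == input_stack.shape == target_stack.shape):
        raise ValueError("predicted, input and target must share a shape")
    desired = np.asarray(input_stack, dtype=np.float64) - np.asarray(
        target_stack, dtype=np.float64
    )
    diff = np.asarray(predicted, dtype=np.float64) - desired
    return float(np.mean(diff * diff))


def _batch_arrays(pairs: Sequence[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_stack for p in pairs]).astype(np.float32)
    y = np.stack([p.target_stack for p in pairs]).astype(np.float32)
    return x, y


def evaluate_epoch(
    model: Model,
    pairs: Sequence[TrainingPair],
    stage: str = "initial",
    epoch: int = 0,
    metric_fns: dict[str, Callable] | None = None,
) -> LossRecord:
    """Validation pass: residual loss with no weight updates (pure)."""
    if not pairs:
        raise ValueError("validation set must be non-empty")
    total, n = 0.0, 0
    by_shape: dict[tuple, list[TrainingPair]] = {}
    for p in pairs:
        by_shape.setdefault(p.input_stack.shape, []).append(p)
    for group in by_shape.values():
        for start in range(0, len(group), 32):
            x, y = _batch_arrays(group[start : start + 32])
            pred = model.forward(x)
            diff = pred.astype(np.float64) - (x.astype(np.float64) - y.astype(np.float64))
            total += float(np.sum(diff * diff))
            n += diff.size
    loss = total / n
    if metric_fns:
        for name, fn in metric_fns.items():
            logger.info("eval %s epoch %d: %s=%.6g", stage, epoch, name, fn(model, pairs))
    return LossRecord(stage, epoch, mean_training_loss=0.0, mean_validation_loss=loss)


def _run_epochs(
    model: Model,
    train_pairs: Sequence[TrainingPair],
    val_pairs: Sequence[TrainingPair],
    config: TrainConfig,
    n_epochs: int,
    stage: str,
    rng: np.random.Generator,
) -> list[LossRecord]:
    opt = Adam(
        model.parameters,
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.eps,
    )
    records: list[LossRecord] = []
    best_val = np.inf
    best_weights = model.copy_weights()
    for epoch in range(1, n_epochs + 1):
        t0 = time.time()
        order = rng.permutation(len(train_pairs))
        epoch_loss, n_px = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = _batch_arrays([train_pairs[i] for i in idx])
            desired = x - y
            pred, caches = model.forward_train(x)
            diff = pred - desired
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            grad = (2.0 / diff.size) * diff
            grads = model.backward(caches, grad)
            opt.step(grads)
            epoch_loss += loss * x.size
            n_px += x.size
        train_loss = epoch_loss / n_px
        val_loss = (
            evaluate_epoch(model, val_pairs, stage, epoch).mean_validation_loss
            if val_pairs
            else train_loss
        )
        records.append(LossRecord(stage, epoch, train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.copy_weights()
        logger.info(
            "stage=%s epoch=%d train_loss=%.6g val_loss=%.6g elapsed=%.1fs",
            stage, epoch, train_loss, val_loss, time.time() - t0,
        )
    model.set_weights(best_weights)  # best-validation checkpoint wins
    return records


def train_initial(
    model: Model, pairs: Sequence[TrainingPair], config: TrainConfig
) -> tuple[Model, list[LossRecord]]:
    """Supervised stage on synthetic noisy-stack -> clean-reference pairs."""
    if not pairs:
        raise ValueError("training set must be non-empty")
    rng = np.random.default_rng(config.seed)
    train_pairs, val_pairs = split_pairs(pairs, config.val_fraction, config.seed)
    records = _run_epochs(
        model, train_pairs, val_pairs, config, config.epochs_initial, "initial", rng
    )
    model.provenance = "initial-trained"
    _maybe_checkpoint(model, config, "initial")
    return model, records


def finetune(
    model: Model, pairs: Sequence[TrainingPair], config: TrainConfig
) -> tuple[Model, list[LossRecord]]:
    """Model-blind noise-to-noise stage on raw 4-frame pairs.

    Re-uses the initially trained weights and retrains the whole network (no
    layer freezing) with noisy targets only.
    """
    if model.provenance not in ("initial-trained", "fine-tuned"):
        raise ValueError("finetune requires an initially trained model")
    if not pairs:
        raise ValueError("fine-tuning set must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    train_pairs, val_pairs = split_pairs(pairs, config.val_fraction, config.seed + 1)
    records = _run_epochs(
        model, train_pairs, val_pairs, config, config.epochs_finetune, "finetune", rng
    )
    model.provenance = "fine-tuned"
    _maybe_checkpoint(model, config, "finetune")
    return model, records


def _maybe_checkpoint(model: Model, config: TrainConfig, stage: str) -> None:
    if config.checkpoint_dir:
        d = Path(config.checkpoint_dir)
        d.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, d / f"{stage}.npz")


def records_to_rows(records: Sequence[LossRecord]) -> list[dict]:
    """Loss history as plain dict rows (for CSV export)."""
    return [
        {
            "stage": r.stage,
            "epoch": r.epoch,
            "train_loss": r.mean_training_loss,
            "val_loss": r.mean_validation_loss,
        }
        for r in records
    ]
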