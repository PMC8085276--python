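"""Run configuration: one nested config object driving the whole workflow.

The defaults describe the desk-scale study: a 128x128, 40 Hz fixed-FOV movie
with ~10 cells, corruption with Poisson magnitude 1 and per-frame Gaussian SD
drawn from (0, 0.05), a reference averaged from 100 frames, supervised
training on 32x32 patches, and the published optimizer settings (Adam,
constant lr 1e-4).  Epoch counts default to the reduced 15 + 5 schedule used
by the bundled study; the full published schedule is 50 + 10.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .simulate import NoiseParams, SceneConfig
from .train import TrainConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Fully resolved configuration for simulate -> train -> evaluate runs."""

    seed: int = 0
    height: int = 128
    width: int = 128
    rate_hz: float = 40.0
    # fixed-FOV movie layout: reference | fine-tune | held-out evaluation
    n_reference_frames: int = 100
    n_finetune_frames: int = 160
    n_eval_frames: int = 40
    gaussian_sd_range: tuple[float, float] = (0.0, 0.05)
    n_supervised_pairs: int = 40
    patch_size: int = 24
    patches_per_pair: int = 8
    scene: SceneConfig = field(default_factory=SceneConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            epochs_initial=15, epochs_finetune=5, batch_size=8
        )
    )
    outdir: str | None = None

    @property
    def n_frames_total(self) -> int:
        return self.n_reference_frames + self.n_finetune_frames + self.n_eval_frames

    def with_seed(self, seed: int) -> "RunConfig":
        """Copy of this config with all stage seeds derived from ``seed``."""
        d = self.to_dict()
        d["seed"] = seed
        d["scene"]["seed"] = seed
        d["noise"]["seed"] = seed + 1
        d["training"]["seed"] = seed + 2
        return RunConfig.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {
            "scene": SceneConfig,
            "noise": NoiseParams,
            "model": ModelConfig,
            "training": TrainConfig,
        }
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for key, value in d.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if key in nested and isinstance(value, dict):
                sub = nested[key]
                base = asdict(cls.__dataclass_fields__[key].default_factory())  # type: ignore[misc]
                base.update(value)
                if "amplitude_range" in base:
                    base["amplitude_range"] = tuple(base["amplitude_range"])
                kwargs[key] = sub(**base)
            elif key == "gaussian_sd_range":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        """Echo the fully resolved configuration next to run outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    """Load a (possibly partial) YAML config; unspecified keys take defaults."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)
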