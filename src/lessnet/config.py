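"""Run configuration: a strict, YAML-serialisable view of every knob.

The configuration round-trips losslessly through YAML, and unknown keys
are rejected with a diagnostic naming the offending key — a typo in a run
file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .augment import STRONG_DEFAULT, WEAK_DEFAULT, AugmentationPolicy
from .data.synthetic import SyntheticConfig
from .losses import LossWeights
from .models import ModelConfig
from .training import TrainConfig


def _from_dict(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"config section '{path}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config key '{path}.{sorted(unknown)[0]}'")
    kwargs = {}
    for key, val in d.items():
        f = names[key]
        default = f.default if f.default is not dataclasses.MISSING else (
            f.default_factory() if f.default_factory is not dataclasses.MISSING else None)
        if dataclasses.is_dataclass(default) and isinstance(val, dict):
            val = _from_dict(type(default), val, f"{path}.{key}")
        elif isinstance(default, tuple) and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


@dataclass
class DataConfig:
    n_images: int = 405
    test_fraction: float = 0.2
    label_ratio: float = 0.5
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


@dataclass
class AugmentationConfig:
    weak: AugmentationPolicy = field(default_factory=lambda: dataclasses.replace(WEAK_DEFAULT))
    strong: AugmentationPolicy = field(default_factory=lambda: dataclasses.replace(STRONG_DEFAULT))
    offline_factor: int = 5
    expand_train_only: bool = True


@dataclass
class EvalConfig:
    ece_bins: int = 15
    spacing: Optional[float] = None
    batch_size: int = 8


@dataclass
class RunConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    # -- (de)serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = _from_dict(cls, d, "config")
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        def _clean(obj: Any):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        text = yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if isinstance(source, Path) or "\n" not in text:
            p = Path(source)
            if p.exists():
                text = p.read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def tiny_test(cls) -> "RunConfig":
        """A configuration sized for fast CPU experiments."""
        return cls(
            data=DataConfig(n_images=40, synthetic=SyntheticConfig(
                image_size=64, lesion_area_fraction_range=(0.02, 0.15))),
            model=ModelConfig.tiny_test(),
            loss=LossWeights(ramp_epochs=5),
            train=TrainConfig(image_size=64, epochs=10, eval_every=5),
        )
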