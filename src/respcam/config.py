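"""Namespaced pipeline configuration with strict YAML loading.

Defaults are the reference values of the method (chest projection
alpha=2.5, beta=0.2; 0.1-0.6 Hz fourth-order band; 0.8/0.2 fusion; 7/5/3
encoder kernels with 8 heads; AdamW lr 1e-3, weight decay 1e-4, batch 32).
Unknown keys are rejected so silent typos cannot change an experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig
from .preprocess import SmoothingParams
from .signals import FilterSpec, FusionWeights
from .spectral import WelchParams

__all__ = ["RoiConfig", "WindowConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class RoiConfig:
    alpha: float = 2.5
    beta: float = 0.2
    mask_chest: bool = True


@dataclass(frozen=True)
class WindowConfig:
    win_len: int = 256
    stride: int = 32

    def __post_init__(self):
        if not (0 < self.stride <= self.win_len):
            raise ValueError("need 0 < stride <= win_len")


@dataclass(frozen=True)
class PipelineConfig:
    roi: RoiConfig = field(default_factory=RoiConfig)
    smooth: SmoothingParams = field(default_factory=SmoothingParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    fusion: FusionWeights = field(default_factory=FusionWeights)
    window: WindowConfig = field(default_factory=WindowConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    welch: WelchParams = field(default_factory=WelchParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


_SECTIONS = {
    "roi": RoiConfig,
    "smooth": SmoothingParams,
    "filter": FilterSpec,
    "fusion": FusionWeights,
    "window": WindowConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "welch": WelchParams,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; missing keys take defaults, unknown keys fail."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    if overrides:
        for key, val in overrides.items():
            section, _, leaf = key.partition(".")
            if leaf:
                data.setdefault(section, {})[leaf] = val
            else:
                data[key] = val
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name, {})) for name, cls in _SECTIONS.items()}
    return PipelineConfig(seed=int(data.get("seed", 0)), **kwargs)
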