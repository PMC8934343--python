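"""YAML pipeline configuration with strict (unknown-key-rejecting) parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .augment import DEFAULT_OPS, AugmentConfig
from .cam_aggregation import AggregationConfig
from .preprocess import CropConfig
from .synthetic import PATTERNS

__all__ = ["PipelineConfig", "TrainSection", "SynthSection", "PathsSection", "load_config"]


def _strict(d: dict | None, allowed: set[str], section: str) -> dict:
    d = d or {}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return d


@dataclass
class TrainSection:
    """Model geometry plus the fine-tuning schedule (defaults at desk scale
    except where the full-scale protocol fixes them: batch 8, patience 10,
    dropout 0.5)."""

    input_size: int = 32
    conv_channels: tuple[int, ...] = (16, 32, 64)
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 8
    patience: int = 10
    max_epochs: int = 60
    steps_per_epoch: int = 0  # 0: one pass over the training images per epoch


@dataclass
class SynthSection:
    classes: tuple[str, ...] = ("blisters", "horizontal_lenticels", "vertical_stripes", "fissures")
    n_per_class: int = 200
    size: int = 96
    nuisance_prob: float = 0.3

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(PATTERNS)
        if bad:
            raise ValueError(f"unknown pattern classes: {sorted(bad)}")


@dataclass
class PathsSection:
    data_dir: str = "data"
    out_dir: str = "runs"


@dataclass
class PipelineConfig:
    seed: int = 0
    crop: CropConfig = field(default_factory=CropConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainSection = field(default_factory=TrainSection)
    cam: AggregationConfig = field(default_factory=AggregationConfig)
    synth: SynthSection = field(default_factory=SynthSection)
    paths: PathsSection = field(default_factory=PathsSection)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = _strict(raw, {"seed", "crop", "augment", "train", "cam", "synth", "paths"}, "<root>")
        sections = {}
        for name, klass in (
            ("crop", CropConfig), ("augment", AugmentConfig), ("train", TrainSection),
            ("cam", AggregationConfig), ("synth", SynthSection), ("paths", PathsSection),
        ):
            fields = {f for f in klass.__dataclass_fields__}
            kwargs = _strict(raw.get(name), fields, name)
            for key in ("magnitude_range", "candidate_ops", "conv_channels", "classes"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            sections[name] = klass(**kwargs)
        return cls(seed=int(raw.get("seed", 0)), **sections)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)
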