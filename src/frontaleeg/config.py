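"""Experiment configuration: one YAML file per experiment.

Every pipeline default lives here so that a single serialized config plus
a seed reproduces an experiment end to end.  Unknown keys are rejected
rather than ignored, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augmentation import AugmentConfig, SEAugmentConfig
from .models import HybridConfig


@dataclass(frozen=True)
class SegmentationConfig:
    window_samples: int = 3840
    overlap_percent: float = 50.0
    fs: float = 250.0
    clip_run_samples: int = 25
    max_removed_fraction: float = 0.20


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.20
    val_fraction: float = 0.15
    seed: int = 42


@dataclass(frozen=True)
class SearchConfig:
    n_trials: int = 12
    top_k: int = 3
    short_epochs: int = 40
    refine_epochs: int = 150
    final_epochs: int = 150
    batch_size: int = 64
    early_stop_patience: int = 15
    plateau_patience: int = 5
    lr_factor: float = 0.5
    min_lr: float = 1e-5


@dataclass(frozen=True)
class SimulateConfig:
    n_hc: int = 12
    n_mdd: int = 8
    duration_s: float = 90.0
    format: str = "csv"  # or "edf"


@dataclass(frozen=True)
class ExperimentConfig:
    data_dir: str = "data"
    output_dir: str = "outputs"
    seed: int = 42
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    se_augment: SEAugmentConfig = field(default_factory=SEAugmentConfig)
    hybrid: HybridConfig = field(default_factory=HybridConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTION_TYPES = {
    "segmentation": SegmentationConfig,
    "split": SplitConfig,
    "search": SearchConfig,
    "simulate": SimulateConfig,
    "augment": AugmentConfig,
    "se_augment": SEAugmentConfig,
    "hybrid": HybridConfig,
}


class ConfigError(ValueError):
    pass


def _build_section(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an ExperimentConfig from YAML, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)
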