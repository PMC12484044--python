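"""Experiment configuration: schema, validation, and seed derivation.

A single YAML file describes an experiment as blocks (data, tokenization,
model, augmentation, train, split).  Unknown keys are rejected at load
time, and the fully resolved configuration (all defaults filled in) is
written back into the output directory of every stage.

One global seed deterministically derives the per-purpose random streams
via ``numpy.random.default_rng([global_seed, STREAM_ID])``; changing e.g.
only the noise stream therefore leaves the generated data untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .training import TrainConfig

__all__ = ["ExperimentConfig", "DataBlock", "TokenizationBlock", "ModelBlock",
           "AugmentationBlock", "SplitBlock", "load_config", "stream_rng",
           "stream_seed", "STREAMS", "config_hash", "write_resolved"]

# documented derivation: rng = default_rng([global_seed, STREAMS[name]])
STREAMS = {
    "data": 0,        # synthetic cohort generation
    "split": 1,       # patient-level splitting / folds
    "init": 2,        # parameter initialization
    "pretrain": 3,    # MLM batch order and corruption
    "finetune": 4,    # fine-tuning batch order
    "noise": 5,       # attention noise / dropout / baseline masks
    "subsample": 6,   # data-insufficiency subsampling
}


def stream_seed(global_seed: int, name: str) -> list[int]:
    return [int(global_seed), STREAMS[name]]


def stream_rng(global_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(global_seed, name))


@dataclass
class DataBlock:
    preset: str | None = "mimic_like"
    path: str | None = None
    n_patients: int = 2000
    overrides: dict = field(default_factory=dict)


@dataclass
class TokenizationBlock:
    min_count: int = 5
    max_len: int = 256
    min_visits: int | None = None
    target_codes: list[str] = field(default_factory=lambda: ["I500"])
    excluded_codes: list[str] = field(default_factory=list)


@dataclass
class ModelBlock:
    d_model: int = 64
    n_heads: int = 4
    d_k: int = 16
    d_v: int = 16
    n_layers: int = 2
    d_ff: int = 256
    dropout: float = 0.0
    use_segment_embedding: bool = False
    pooling: str = "mean"


@dataclass
class AugmentationBlock:
    mode: str = "none"               # none | RNA | ANAA
    sigma_eh: float = 1.0
    kernel_normalized: bool = True
    variance_denominator: str = "elements_minus_one"
    baseline: dict | None = None     # mutually exclusive with mode != none


@dataclass
class SplitBlock:
    fractions: list[float] = field(default_factory=lambda: [0.7, 0.2, 0.1])
    k_folds: int = 5


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "anaa_out"
    data: DataBlock = field(default_factory=DataBlock)
    tokenization: TokenizationBlock = field(default_factory=TokenizationBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    augmentation: AugmentationBlock = field(default_factory=AugmentationBlock)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitBlock = field(default_factory=SplitBlock)


def _build(cls, data: dict, path: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"config block {path!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(names))
    if unknown:
        raise ValueError(f"unknown config keys under {path!r}: {unknown}")
    return cls(**data)


_BLOCK_TYPES = {"data": DataBlock, "tokenization": TokenizationBlock,
                "model": ModelBlock, "augmentation": AugmentationBlock,
                "train": TrainConfig, "split": SplitBlock}


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> ExperimentConfig:
    """Load and validate an experiment config from YAML (or a dict)."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    top = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = sorted(set(data) - top)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {unknown}")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCK_TYPES:
            kwargs[key] = _build(_BLOCK_TYPES[key], value or {}, key)
        else:
            kwargs[key] = value
    cfg = ExperimentConfig(**kwargs)
    if (cfg.augmentation.baseline is not None
            and cfg.augmentation.mode != "none"):
        raise ValueError("augmentation.mode and augmentation.baseline are "
                         "mutually exclusive")
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_resolved(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config (defaults filled) into the output
    directory; every stage calls this so runs are self-describing."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.yaml"
    plain = json.loads(json.dumps(asdict(cfg)))  # tuples -> lists for YAML
    path.write_text(yaml.safe_dump(plain, sort_keys=False))
    return path
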