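"""Structured run configuration: YAML in, validated dataclasses out.

A run config has one section per pipeline stage.  Unknown keys are
rejected rather than ignored so a typo never silently reverts a parameter
to its default.  The fully resolved config is serialized next to every
run's outputs, making any artifact regenerable from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .objectives import LossWeights
from .synthetic import SyntheticSpec
from .train import TrainConfig


@dataclass(frozen=True)
class EvalConfig:
    tta: int = 8
    bootstrap_B: int = 2000
    average: str = "probability"  # TTA aggregation: probability | logit


@dataclass(frozen=True)
class SplitConfig:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "runs/default"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "synthetic": enc(self.synthetic),
            "split": enc(self.split),
            "model": enc(self.model),
            "train": enc(self.train),
            "eval": enc(self.eval),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "synthetic": SyntheticSpec,
    "split": SplitConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "eval": EvalConfig,
}
_TUPLE_KEYS = {"grade_marginals", "fractions", "crop_scale", "crop_aspect"}


def _build_section(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_KEYS and isinstance(v, list):
            v = tuple(v)
        if k == "loss_weights" and isinstance(v, dict):
            v = _build_section(LossWeights, v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - (set(_SECTIONS) | {"seed", "out_dir"})
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig(
        seed=int(data.get("seed", 42)),
        out_dir=str(data.get("out_dir", "runs/default")),
    )
    for name, cls in _SECTIONS.items():
        if name in data:
            setattr(cfg, name, _build_section(cls, dict(data[name] or {})))
    return cfg
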