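"""Strict-schema run configuration for the end-to-end pipeline.

A single global seed deterministically derives per-stage seeds (stable
hash of stage name + seed), so stages can be rerun independently yet
reproducibly. Unknown keys are errors, listed all at once; an empty file
is an error, not silent defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, fields
from typing import Optional

import yaml

from .cdl import CDLConfig
from .selection import HJWOAConfig
from .stain import SplitSpec
from .synthetic import TileGenParams

__all__ = ["RunConfig", "load_config", "save_config", "stage_seed", "ConfigError"]

CONFIG_VERSION = "1"

#: Pipeline stage order.
STAGES = ("simulate", "normalize", "extract_features", "select_features",
          "train", "evaluate")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"
    stages: tuple = STAGES
    n_train_tiles: int = 24
    n_val_tiles: int = 8
    n_test_tiles: int = 8
    tile: TileGenParams = field(default_factory=TileGenParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    hjwoa: HJWOAConfig = field(default_factory=HJWOAConfig)
    cdl: CDLConfig = field(default_factory=CDLConfig)
    version: str = CONFIG_VERSION

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


_NESTED = {"tile": TileGenParams, "split": SplitSpec,
           "hjwoa": HJWOAConfig, "cdl": CDLConfig}


def load_config(path) -> RunConfig:
    """Strict YAML parse; every offending key is reported."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"config file {path} is empty")
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a mapping")

    errors = []
    top_fields = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in top_fields:
            errors.append(key)
    kwargs = {}
    for key, value in raw.items():
        if key in errors:
            continue
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in fields(cls)}
            bad = [f"{key}.{k}" for k in value if k not in sub_fields]
            if bad:
                errors.extend(bad)
                continue
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    if errors:
        raise ConfigError(f"unknown config key(s): {sorted(errors)}")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
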