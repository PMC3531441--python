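"""Configuration: a flat dataclass mirroring the CLI flags, YAML-loadable.

CLI flags override file values; unknown keys are rejected early.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class Config:
    seed: int = 0
    n_trees: int = 100
    fold_engine: str = "vienna"
    loop_split: str = "arm5"  # arm5 | maxarm
    train_margin: int = 1
    train_balance: bool = False
    dicer_refold: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fold_engine != "vienna":
            raise ValueError(
                f"fold.engine {self.fold_engine!r} not available (only 'vienna')"
            )
        if self.loop_split not in ("arm5", "maxarm"):
            raise ValueError(f"profile.loop_split must be arm5|maxarm")


#: YAML key -> Config field (dotted keys mirror the module structure)
_KEY_MAP = {
    "seed": "seed",
    "trees": "n_trees",
    "fold.engine": "fold_engine",
    "profile.loop_split": "loop_split",
    "train.margin": "train_margin",
    "train.balance": "train_balance",
    "dicer.refold": "dicer_refold",
    "log.level": "log_level",
}


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> Config:
    """Build a Config from an optional YAML file plus keyword overrides
    (override values of None are ignored)."""
    values: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        for key, val in _flatten(raw).items():
            if key not in _KEY_MAP:
                raise ValueError(f"{path}: unknown config key {key!r}")
            values[_KEY_MAP[key]] = val
    field_names = {f.name for f in dataclasses.fields(Config)}
    for key, val in overrides.items():
        if key not in field_names:
            raise ValueError(f"unknown config override {key!r}")
        if val is not None:
            values[key] = val
    return Config(**values)
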