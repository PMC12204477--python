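"""Run configuration for the command-line interface (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputNotFoundError, ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    omega: int = 100
    a_omega: float = 0.5
    oadr_percent: bool = True          # x100 display convention in table reports
    interval: int = 50                 # default SO/NSA comparison interval, years
    units_scale: float = 1.0           # multiplier for population counts (e.g. 1000)
    lifetable_columns: dict = field(default_factory=dict)
    population_columns: dict = field(default_factory=dict)
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValidationError(f"interval must be positive, got {self.interval}")
        if self.omega < 1:
            raise ValidationError(f"omega must be at least 1, got {self.omega}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
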