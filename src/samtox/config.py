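"""Run configuration shared by the CLI subcommands (YAML round-trip)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import InputError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline settings: effect levels (percent), capacity shape, the
    environmental-mortality grid of the overall prediction, pre-processing
    toggles and the random seed."""

    x_levels: list = field(default_factory=lambda: [10.0, 50.0])
    shape: float = 3.2
    env_grid: list = field(default_factory=lambda: [
        0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90])
    williams: bool = True
    interpolate: int | None = 10
    fix_c: bool = True
    fix_d: bool = True
    shape_bounds: list = field(default_factory=lambda: [1.0, 20.0])
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.shape <= 0:
            raise InputError(f"field 'shape': must be > 0, got {self.shape}")
        for x in self.x_levels:
            if not 0 < x < 100:
                raise InputError(f"field 'x_levels': effect percents must lie in (0, 100), got {x}")
        for m in self.env_grid:
            if not 0 <= m < 1:
                raise InputError(f"field 'env_grid': mortalities must lie in [0, 1), got {m}")
        if self.interpolate is not None and self.interpolate < 2:
            raise InputError(f"field 'interpolate': need >= 2 points, got {self.interpolate}")
        if not (len(self.shape_bounds) == 2 and 0 < self.shape_bounds[0] < self.shape_bounds[1]):
            raise InputError(f"field 'shape_bounds': need 0 < lo < hi, got {self.shape_bounds}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise InputError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text
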