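"""Run configuration: flat key-value YAML, validated on load."""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .constants import R_GAS
from .errors import SchemaError
from .kinetics import DEFAULT_DELTA_R2
from .predict import CalibrationEnvelope, _default_hard, _default_soft


@dataclass
class RunConfig:
    """All tunable run-level settings.

    Unknown keys in a config file are rejected, so typos fail loudly.
    Envelope keys are flat: ``soft_t_min_C`` .. ``hard_time_max_min``.
    """

    gas_constant: float = R_GAS
    density_table: str | None = None  # path; None -> bundled table
    time_unit: str = "s"  # "s" or "min" for series inputs
    delta_r2: float = DEFAULT_DELTA_R2
    strict: bool = False
    soft_t_min_C: float = 30.0
    soft_t_max_C: float = 40.0
    soft_w_min: float = 88.0
    soft_w_max: float = 98.0
    soft_time_max_min: float = 4.7
    hard_t_min_C: float = 0.0
    hard_t_max_C: float = 45.0
    hard_w_min: float = 80.0
    hard_w_max: float = 100.0
    hard_time_max_min: float = 15.0
    t_step_s: float = 30.0
    temp_step_C: float = 2.5
    w_step: float = 1.0

    def __post_init__(self):
        if self.time_unit not in ("s", "min"):
            raise SchemaError(f"time_unit must be 's' or 'min', got {self.time_unit!r}")
        if self.gas_constant <= 0:
            raise SchemaError("gas_constant must be positive")
        if self.delta_r2 < 0:
            raise SchemaError("delta_r2 must be >= 0")

    def envelope(self) -> CalibrationEnvelope:
        soft = _default_soft()
        hard = _default_hard()
        soft.update(
            t_min=self.soft_t_min_C + 273.15,
            t_max=self.soft_t_max_C + 273.15,
            w_min=self.soft_w_min,
            w_max=self.soft_w_max,
            time_max=self.soft_time_max_min * 60.0,
        )
        hard.update(
            t_min=self.hard_t_min_C + 273.15,
            t_max=self.hard_t_max_C + 273.15,
            w_min=self.hard_w_min,
            w_max=self.hard_w_max,
            time_max=self.hard_time_max_min * 60.0,
        )
        return CalibrationEnvelope(soft=soft, hard=hard)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise SchemaError("config file must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
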