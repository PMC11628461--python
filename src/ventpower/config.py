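"""Validated run configuration for the command-line interface.

A run is described either by CLI flags, by a YAML config file, or both
(flags override the file).  The pydantic model performs all cross-field
validation up front so the CLI can fail with a message naming the offending
field before any computation starts.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .mechanics import RespiratoryMechanics
from .optimize import SearchSpace


class RunConfig(BaseModel):
    """All parameters of one CLI run (units as package-wide conventions)."""

    # patient-side mechanics
    elastance: float = Field(gt=0, description="respiratory-system elastance, mbar/L")
    airway_resistance: float = Field(default=1.0, ge=0, description="mbar/L/s")
    tube_resistance: float = Field(default=7.0, ge=0, description="mbar/L/s")
    dead_space: float = Field(default=0.2, gt=0, description="anatomic dead space, L")

    # patient scale / targets
    alveolar_ventilation: float = Field(default=10.0, gt=0, description="L/min")
    peep: float = Field(default=0.0, ge=0, description="external PEEP, mbar")
    body_weight: Optional[float] = Field(default=None, gt=0, description="kg")

    # search space and objective
    vt_min: Optional[float] = Field(default=None, gt=0, description="L; default V_D + 0.01")
    vt_max: float = Field(default=2.0, gt=0, description="L")
    vt_step: float = Field(default=0.001, gt=0, description="L")
    ie_min: float = Field(default=0.1, gt=0)
    ie_max: float = Field(default=4.0, gt=0)
    objective: Literal["total", "elastic"] = "total"
    ie_mode: Literal["optimize", "fixed"] = "optimize"
    ie_fixed: float = Field(default=1.0, gt=0, description="used when ie_mode='fixed'")

    # output behaviour
    out_dir: str = "."
    strict: bool = False
    verbose: bool = False
    plot: bool = False

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if self.airway_resistance + self.tube_resistance < 0:
            raise ValueError("total resistance must be >= 0")
        if self.vt_min is not None and self.vt_min <= self.dead_space:
            raise ValueError(
                f"vt_min ({self.vt_min} L) must exceed dead_space ({self.dead_space} L)"
            )
        if self.vt_max <= (self.vt_min or self.dead_space):
            raise ValueError("vt_max must exceed vt_min")
        if self.ie_max <= self.ie_min:
            raise ValueError("ie_max must exceed ie_min")
        return self

    def mechanics(self) -> RespiratoryMechanics:
        return RespiratoryMechanics(
            elastance=self.elastance,
            airway_resistance=self.airway_resistance,
            tube_resistance=self.tube_resistance,
            dead_space=self.dead_space,
        )

    def search_space(self) -> SearchSpace:
        return SearchSpace(
            vt_min=self.vt_min if self.vt_min is not None else self.dead_space + 0.01,
            vt_max=self.vt_max,
            vt_step=self.vt_step,
            ie_min=self.ie_min,
            ie_max=self.ie_max,
        )

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
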