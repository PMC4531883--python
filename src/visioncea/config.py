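"""Run configuration: YAML loading with schema validation and base-case defaults.

A :class:`RunConfig` pins everything a full pipeline run needs — life-table
source, model parameters, and analysis settings (iteration count, seed,
willingness-to-pay grid, scenario lists) — so that a recorded config plus a
seed fully determines every output.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .cohort import ModelParams
from .life_tables import (
    GOMPERTZ_DEFAULTS,
    LifeTable,
    make_gompertz_life_table,
    read_life_table,
)
from .uncertainty import DEFAULT_FIRST_YEAR_COSTS, DEFAULT_RR_SCENARIOS

__all__ = ["RunConfig", "LifeTableConfig", "ParamsConfig", "AnalysisConfig",
           "ConfigError", "load_config"]

#: Currency-year label attached to all monetary outputs.
CURRENCY_LABEL = "EUR-2014"


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LifeTableConfig(_StrictModel):
    """Where mortality comes from: a file path or synthetic constants."""

    path: str | None = None
    gompertz_a: float = GOMPERTZ_DEFAULTS["a"]
    gompertz_b: float = GOMPERTZ_DEFAULTS["b"]
    makeham_c: float = GOMPERTZ_DEFAULTS["c"]
    min_age: int = GOMPERTZ_DEFAULTS["min_age"]
    max_age: int = GOMPERTZ_DEFAULTS["max_age"]

    def build(self) -> LifeTable:
        if self.path is not None:
            return read_life_table(self.path)
        return make_gompertz_life_table(
            a=self.gompertz_a, b=self.gompertz_b, c=self.makeham_c,
            min_age=self.min_age, max_age=self.max_age,
        )


class ParamsConfig(_StrictModel):
    """Deterministic base-case model parameters (EUR-2014 prices)."""

    start_age: int = 51
    horizon: int | Literal["lifetime"] = "lifetime"
    discount_costs: float = Field(0.03, ge=0)
    discount_effects: float = Field(0.03, ge=0)
    cost_blind: float = Field(4091.0, ge=0)
    cost_vimp: float = Field(3680.0, ge=0)
    utility_blind: float = Field(0.61, ge=0, le=1)
    utility_vimp: float = Field(0.77, ge=0, le=1)
    avd_first_year_cost: float = Field(85_000.0, ge=0)
    avd_followup_cost: float = Field(1_500.0, ge=0)
    responder_rate: float = Field(0.625, ge=0, le=1)
    half_cycle_correction: bool = False
    followup_all_alive: bool = True

    @field_validator("horizon")
    @classmethod
    def _horizon_positive(cls, v):
        if v != "lifetime" and v < 1:
            raise ValueError("horizon must be 'lifetime' or a positive integer")
        return v

    def build(self) -> ModelParams:
        return ModelParams(**self.model_dump())


class AnalysisConfig(_StrictModel):
    """Settings for the stochastic and scenario analyses."""

    n_iter: int = Field(1000, ge=1)
    seed: int = Field(0, ge=0)
    wtp_grid: list[float] = Field(
        default_factory=lambda: [float(w) for w in range(0, 200_001, 5_000)]
    )
    rr_scenarios: list[float] = Field(default_factory=lambda: list(DEFAULT_RR_SCENARIOS))
    first_year_cost_scenarios: list[float] = Field(
        default_factory=lambda: list(DEFAULT_FIRST_YEAR_COSTS)
    )

    @field_validator("wtp_grid", "rr_scenarios", "first_year_cost_scenarios")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("list must be non-empty")
        return v


class RunConfig(_StrictModel):
    """Validated top-level configuration; defaults equal the base case."""

    life_table: LifeTableConfig = Field(default_factory=LifeTableConfig)
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output_dir: str = "results"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An absent path or empty file yields the full base-case defaults.
    Schema violations raise :class:`ConfigError` listing the offending keys.
    """
    data = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({locs}): {exc}") from exc
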