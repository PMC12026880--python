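"""Strict run configuration (YAML) for the pipeline CLI."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .synth import CohortPlan, default_plan
from .types import DEFAULT_LOG_OUTCOMES, OUTCOMES, ValidationError


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_participants: Optional[int] = None   # default: plan's included count
    n_days: Optional[int] = None           # default: plan's calendar length


class ExtractConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    include_partial: bool = False


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outcomes: list[str] = Field(default_factory=lambda: list(OUTCOMES))
    day_types: list[str] = Field(default_factory=lambda: ["workday", "leisure"])
    references: list[str] = Field(default_factory=lambda: ["SB", "LPA", "MVPA", "sleep"])
    delta: float = 30.0
    covariates: list[str] = Field(default_factory=lambda: ["age", "alcohol"])
    log_outcomes: list[str] = Field(default_factory=lambda: sorted(DEFAULT_LOG_OUTCOMES))
    log_base: float = 10.0
    alpha: float = 0.05
    vif_threshold: float = 5.0
    families: list[str] = Field(default_factory=lambda: ["isotemporal", "single_factor"])


class ReportConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outcomes: Optional[list[str]] = None   # arrow-summary outcome columns


class RunConfig(BaseModel):
    """Top-level config; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    plan: CohortPlan = Field(default_factory=default_plan)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    extract: ExtractConfig = Field(default_factory=ExtractConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load and strictly validate a YAML config; ``None`` gives defaults."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        try:
            cfg = RunConfig(**raw)
        except PydanticValidationError as exc:
            raise ValidationError(f"{path}: invalid config: {exc}") from exc
    if not cfg.plan.outcomes:
        cfg.plan = default_plan(**cfg.plan.model_dump(exclude={"outcomes"}))
    return cfg
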