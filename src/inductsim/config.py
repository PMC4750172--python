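"""Pipeline configuration: schema, validation, YAML IO and the packaged
base case.

The packaged ``paper_basecase`` configuration carries the published
model inputs: the Southmead cohort composition (1397 inductions out of
6140 annual births; 741 parous, 656 nulliparous), the per-stratum 12/24-h
vaginal-delivery proportions and per-arm caesarean rates and mean times
to vaginal delivery, the treatment-related adverse-event rates, the
care-schedule parameters and the staffing assumptions.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .adverse_events import AE_EVENTS
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config", "load_basecase", "paper_basecase"]

CONFIG_SCHEMA_VERSION = 1

Arm = Literal["DVI", "MVI"]
Parity = Literal["parous", "nulliparous"]


class CohortBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_total: int = Field(gt=0)
    parous: int = Field(ge=0)
    nulliparous: int = Field(ge=0)
    annual_births: int = Field(gt=0)

    @model_validator(mode="after")
    def _parity_sums(self) -> "CohortBlock":
        if self.parous + self.nulliparous != self.n_total:
            raise ValueError(
                f"parity counts {self.parous}+{self.nulliparous} do not sum to {self.n_total}")
        return self


class AnchorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_vd_12h: float = Field(ge=0, lt=1)
    p_vd_24h: float = Field(gt=0, lt=1)


class ArmClinicalBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cs_total: float = Field(ge=0, lt=1)
    mean_vd_h: float | None = Field(default=None, gt=0)
    median_vd_h: float | None = Field(default=None, gt=0)
    oxytocin_prob: float = Field(ge=0, le=1)
    oxytocin_duration_h: float = Field(ge=0)
    anchors: dict[Parity, AnchorBlock]

    @model_validator(mode="after")
    def _has_both_parities(self) -> "ArmClinicalBlock":
        missing = {"parous", "nulliparous"} - set(self.anchors)
        if missing:
            raise ValueError(f"missing anchor blocks for {sorted(missing)}")
        return self


class CalibrationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["weibull", "log_logistic", "piecewise_exponential"] = "piecewise_exponential"
    calibrate_tail_to_mean: bool = True
    active_labour_first_stage_h: float = Field(default=4.0, ge=0)
    active_labour_second_stage_h: float = Field(default=1.0, ge=0)


class ScheduleBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ve_duration_min: float = Field(default=10.0, gt=0)
    ve_interval_active_h: float = Field(default=4.0, gt=0)
    ve_interval_active_oxytocin_h: float = Field(default=3.0, gt=0)
    vsm_duration_min: float = Field(default=3.0, gt=0)
    vsm_interval_pre_active_h: float = Field(default=4.0, gt=0)
    vsm_interval_stage1_h: float = Field(default=4.0, gt=0)
    vsm_interval_stage2_h: float = Field(default=1.0, gt=0)
    oxytocin_setup_min_per_midwife: float = Field(default=10.0, gt=0)
    oxytocin_setup_midwives: int = Field(default=2, ge=1)


class StaffingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shift_length_h: float = Field(default=8.0, gt=0)
    current_births_per_midwife: float = Field(default=33.0, gt=0)
    recommended_ratio: float = Field(default=29.5, gt=0)


class SensitivityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    parameters: list[str] = Field(default_factory=lambda: [
        "ve_duration", "vsm_duration", "oxytocin_setup_duration", "ve_frequency"])
    factors: list[float] = Field(default_factory=lambda: [0.5, 1.0, 1.5])


class PipelineConfig(BaseModel):
    """Validated, versioned model configuration."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = CONFIG_SCHEMA_VERSION
    cohort: CohortBlock
    arms: dict[Arm, ArmClinicalBlock]
    ae_rates: dict[Arm, dict[str, float]]
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    staffing: StaffingBlock = Field(default_factory=StaffingBlock)
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)
    inpatient_stay_h: float = Field(default=6.0, ge=0)
    horizon: int = Field(default=168, ge=1)
    seed: int = 12345

    @model_validator(mode="after")
    def _check_blocks(self) -> "PipelineConfig":
        missing_arms = {"DVI", "MVI"} - set(self.arms)
        if missing_arms:
            raise ValueError(f"missing arm blocks {sorted(missing_arms)}")
        for arm in ("DVI", "MVI"):
            rates = self.ae_rates.get(arm, {})
            missing = set(AE_EVENTS) - set(rates)
            if missing:
                raise ValueError(f"AE rates for {arm} missing events {sorted(missing)}")
            bad = {e: r for e, r in rates.items() if not 0.0 <= r <= 1.0}
            if bad:
                raise ValueError(f"AE rates for {arm} outside [0, 1]: {bad}")
        return self

    def stratum_sizes(self) -> dict[str, int]:
        return {"parous": self.cohort.parous, "nulliparous": self.cohort.nulliparous}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    """Load and schema-validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_basecase() -> PipelineConfig:
    """The packaged base-case configuration with all published inputs."""
    ref = importlib.resources.files("inductsim").joinpath("data/paper_basecase.yaml")
    raw = yaml.safe_load(ref.read_text())
    return PipelineConfig.model_validate(raw)


# backwards-friendly alias used in examples
paper_basecase = load_basecase
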