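"""Deterministic sensitivity and scenario analysis of the care schedule.

Clinical traces (delivery-time distributions) are held fixed: only the
care-process parameters are perturbed, one at a time and jointly at the
corners, by multiplicative factors (default +/-50 %).  The
vaginal-examination frequency perturbation scales the examination
*interval* (a factor of 0.5 means examinations twice as often).

The continuous-monitoring scenario puts every woman induced with the
misoprostol insert on the with-oxytocin examination schedule, leaving
the dinoprostone arm unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .cohort import CohortTrace
from .errors import ConfigurationError
from .resources import (
    ResourceComparison,
    ResourceSchedule,
    StaffingModel,
    aggregate_workload,
    compare_resources,
)

__all__ = ["SENSITIVITY_PARAMETERS", "SensitivitySpec", "SensitivityGrid",
           "perturb_schedule", "run_dsa", "scenario_continuous_monitoring"]

#: perturbable parameters and the schedule fields they scale
SENSITIVITY_PARAMETERS = {
    "ve_duration": ("ve_duration_min",),
    "vsm_duration": ("vsm_duration_min",),
    "oxytocin_setup_duration": ("oxytocin_setup_min_per_midwife",),
    "ve_frequency": ("ve_interval_active_h", "ve_interval_active_oxytocin_h"),
}

DURATION_PARAMETERS = ("ve_duration", "vsm_duration", "oxytocin_setup_duration")


@dataclass(frozen=True)
class SensitivitySpec:
    parameters: tuple[str, ...] = tuple(SENSITIVITY_PARAMETERS)
    factors: tuple[float, ...] = (0.5, 1.0, 1.5)
    mode: str = "one_way"

    def __post_init__(self) -> None:
        unknown = set(self.parameters) - set(SENSITIVITY_PARAMETERS)
        if unknown:
            raise ConfigurationError(f"unknown sensitivity parameters {sorted(unknown)}")
        if any(f <= 0 for f in self.factors):
            raise ConfigurationError("perturbation factors must be > 0")
        if 1.0 not in self.factors:
            raise ConfigurationError("factor set must include the base case 1.0")


def perturb_schedule(schedule: ResourceSchedule,
                     factors_by_parameter: dict[str, float]) -> ResourceSchedule:
    """Scale the named schedule parameters by the given factors."""
    changes: dict[str, float] = {}
    for param, factor in factors_by_parameter.items():
        if param not in SENSITIVITY_PARAMETERS:
            raise ConfigurationError(f"unknown sensitivity parameter {param!r}")
        for fld in SENSITIVITY_PARAMETERS[param]:
            changes[fld] = getattr(schedule, fld) * factor
    return replace(schedule, **changes)


@dataclass
class SensitivityGrid:
    """Long-format grid of perturbed-schedule outcomes."""

    table: pd.DataFrame   # columns: label, parameter(s), factor, shifts per arm, deltas
    base_row_label: str = "base"

    @property
    def base_row(self) -> pd.Series:
        return self.table.loc[self.table["label"] == self.base_row_label].iloc[0]

    def worst_case(self) -> pd.Series:
        return self.table.loc[self.table["shifts_saved"].idxmin()]

    def best_case(self) -> pd.Series:
        return self.table.loc[self.table["shifts_saved"].idxmax()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _evaluate(dvi_traces, mvi_traces, schedule, staffing) -> dict[str, float]:
    dvi = aggregate_workload(dvi_traces, schedule, staffing)
    mvi = aggregate_workload(mvi_traces, schedule, staffing)
    comp = compare_resources(dvi, mvi, staffing)
    return {
        "shifts_dvi": dvi.total_shifts,
        "shifts_mvi": mvi.total_shifts,
        "shifts_saved": comp.shifts_saved,
        "bed_hours_saved": comp.bed_hours_saved,
    }


def run_dsa(
    dvi_traces: Sequence[CohortTrace],
    mvi_traces: Sequence[CohortTrace],
    schedule: ResourceSchedule,
    staffing: StaffingModel,
    spec: SensitivitySpec | None = None,
) -> SensitivityGrid:
    """One-way perturbations plus all-durations and all-parameters corners.

    The grid always contains the unperturbed base case, which is
    bit-identical to a standalone base-case evaluation.
    """
    spec = spec or SensitivitySpec()
    rows = []

    def add_row(label: str, params: dict[str, float]) -> None:
        sched = perturb_schedule(schedule, params)
        row = {"label": label,
               "parameters": ";".join(f"{p}={f:g}" for p, f in params.items()) or "-"}
        row.update(_evaluate(dvi_traces, mvi_traces, sched, staffing))
        rows.append(row)

    add_row("base", {})
    for param in spec.parameters:
        for f in spec.factors:
            if f == 1.0:
                continue
            add_row(f"{param}_x{f:g}", {param: f})
    for f in spec.factors:
        if f == 1.0:
            continue
        durations = [p for p in DURATION_PARAMETERS if p in spec.parameters]
        if durations:
            add_row(f"all_durations_x{f:g}", {p: f for p in durations})
        if set(spec.parameters) - set(durations):
            add_row(f"all_parameters_x{f:g}", {p: f for p in spec.parameters})

    table = pd.DataFrame(rows)
    base = table.loc[table["label"] == "base", "shifts_saved"].iloc[0]
    table["delta_shifts_saved_vs_base"] = table["shifts_saved"] - base
    return SensitivityGrid(table=table)


def scenario_continuous_monitoring(
    dvi_traces: Sequence[CohortTrace],
    mvi_traces: Sequence[CohortTrace],
    schedule: ResourceSchedule,
    staffing: StaffingModel,
    apply_to_dvi: bool = False,
) -> ResourceComparison:
    """Continuous monitoring for the misoprostol arm.

    Staff involvement is taken as equivalent to monitoring a woman on
    oxytocin: every woman in the arm follows the with-oxytocin
    examination schedule.  ``apply_to_dvi`` extends the same assumption
    to the comparator arm (symmetry control)."""
    dvi = aggregate_workload(dvi_traces, schedule, staffing,
                             monitor_all_as_oxytocin=apply_to_dvi)
    mvi = aggregate_workload(mvi_traces, schedule, staffing,
                             monitor_all_as_oxytocin=True)
    return compare_resources(dvi, mvi, staffing)
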