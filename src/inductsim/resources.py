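"""Midwife workload, bed occupancy and ward-capacity accounting.

Care events follow the hospital's observed schedule: a 10-minute vaginal
examination once on admission to pre-active labour and at fixed
intervals during active labour (every 4 h, or every 3 h for women on
oxytocin), 3-minute vital-signs observations every 4 h in pre-active
labour and the first stage and hourly in the second stage, and a
two-midwife, 10-minutes-each oxytocin set-up.  Scheduled events use the
completed-interval convention: an event fires at each whole multiple of
the interval elapsed within the state (the admission examination fires
at state entry), which is deterministic and checkable against
hour-by-hour enumeration.

Workload is integrated over the expected delivery-time distribution of a
cohort trace; minutes convert to midwife shifts with a configurable
shift length.  Labour-suite bed occupancy runs from induction to
delivery (mid-cycle convention); the postnatal stay is tracked
separately and enters only the per-induction bed footprint used for the
capacity calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortTrace, _stage_durations
from .errors import ConfigurationError

__all__ = [
    "ResourceSchedule",
    "StaffingModel",
    "ResourceResult",
    "ResourceComparison",
    "midwife_minutes_for_pathway",
    "aggregate_workload",
    "bed_occupancy",
    "capacity_gain",
    "births_per_midwife_adjusted",
    "compare_resources",
]

ACTIVITIES = ("vaginal_examination", "vital_signs_monitoring", "oxytocin_setup")


@dataclass(frozen=True)
class ResourceSchedule:
    """Care-event durations (minutes) and frequencies (hour intervals)."""

    ve_duration_min: float = 10.0
    ve_interval_active_h: float = 4.0
    ve_interval_active_oxytocin_h: float = 3.0
    vsm_duration_min: float = 3.0
    vsm_interval_pre_active_h: float = 4.0
    vsm_interval_stage1_h: float = 4.0
    vsm_interval_stage2_h: float = 1.0
    oxytocin_setup_min_per_midwife: float = 10.0
    oxytocin_setup_midwives: int = 2

    def __post_init__(self) -> None:
        for name in ("ve_duration_min", "vsm_duration_min", "oxytocin_setup_min_per_midwife"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("ve_interval_active_h", "ve_interval_active_oxytocin_h",
                     "vsm_interval_pre_active_h", "vsm_interval_stage1_h",
                     "vsm_interval_stage2_h"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.oxytocin_setup_midwives < 1:
            raise ConfigurationError("oxytocin_setup_midwives must be >= 1")


@dataclass(frozen=True)
class StaffingModel:
    """Shift length and the hospital's births-per-midwife context."""

    shift_length_h: float = 8.0
    current_births_per_midwife: float = 33.0
    recommended_ratio: float = 29.5

    def __post_init__(self) -> None:
        if self.shift_length_h <= 0:
            raise ConfigurationError("shift_length_h must be > 0")
        if self.current_births_per_midwife <= 0 or self.recommended_ratio <= 0:
            raise ConfigurationError("ratios must be > 0")


def midwife_minutes_for_pathway(
    pre_active_h: float,
    active1_h: float,
    active2_h: float,
    oxytocin: bool,
    schedule: ResourceSchedule,
) -> dict[str, float]:
    """Midwife-minutes by activity for one woman's labour pathway.

    Event counts follow the completed-interval convention; the single
    pre-active examination fires on entry regardless of duration.
    """
    if min(pre_active_h, active1_h, active2_h) < 0:
        raise ConfigurationError("state durations must be >= 0")
    ve_interval = (schedule.ve_interval_active_oxytocin_h if oxytocin
                   else schedule.ve_interval_active_h)
    active_h = active1_h + active2_h
    n_ve = 1 + math.floor(active_h / ve_interval)
    n_vsm = (
        math.floor(pre_active_h / schedule.vsm_interval_pre_active_h)
        + math.floor(active1_h / schedule.vsm_interval_stage1_h)
        + math.floor(active2_h / schedule.vsm_interval_stage2_h)
    )
    setup = (schedule.oxytocin_setup_midwives * schedule.oxytocin_setup_min_per_midwife
             if oxytocin else 0.0)
    return {
        "vaginal_examination": n_ve * schedule.ve_duration_min,
        "vital_signs_monitoring": n_vsm * schedule.vsm_duration_min,
        "oxytocin_setup": setup,
    }


@dataclass
class ResourceResult:
    """Aggregate workload and occupancy for one arm."""

    arm: str
    n_women: float
    minutes_by_activity: dict[str, float]
    shift_length_h: float
    bed_hours: float
    bed_hours_by_parity: dict[str, float]
    mean_bed_hours_per_induction: float
    mean_pathway_bed_hours_per_induction: float  # includes postnatal stay

    @property
    def total_minutes(self) -> float:
        return sum(self.minutes_by_activity.values())

    @property
    def shifts_by_activity(self) -> dict[str, float]:
        m = 60.0 * self.shift_length_h
        return {k: v / m for k, v in self.minutes_by_activity.items()}

    @property
    def total_shifts(self) -> float:
        return self.total_minutes / (60.0 * self.shift_length_h)

    @property
    def bed_days(self) -> int:
        return round(self.bed_hours / 24.0)


def aggregate_workload(
    traces: Sequence[CohortTrace],
    schedule: ResourceSchedule,
    staffing: StaffingModel,
    monitor_all_as_oxytocin: bool = False,
) -> ResourceResult:
    """Expected workload for one arm, integrated over the traces'
    delivery-time distributions and the fixed oxytocin split.

    ``monitor_all_as_oxytocin`` puts every woman on the with-oxytocin
    examination schedule (continuous-monitoring scenario) while the
    set-up task still applies only to actual oxytocin recipients.
    """
    arms = {t.profile.arm for t in traces}
    if len(arms) != 1:
        raise ConfigurationError(f"traces span multiple arms {sorted(arms)}")
    minutes = {a: 0.0 for a in ACTIVITIES}
    bed_by_parity: dict[str, float] = {}
    n_total = 0.0
    bed_total = 0.0
    stay_weighted = 0.0
    for tr in traces:
        n_total += tr.n_women
        t = np.arange(tr.horizon)
        pre_h, s1_h, s2_h = _stage_durations(t)
        atoms = tr.atoms_all
        p_oxy = tr.profile.oxytocin_prob
        groups = (
            (p_oxy, True, True),
            (1.0 - p_oxy, monitor_all_as_oxytocin, False),
        )
        for weight, oxy_monitoring, oxy_setup in groups:
            if weight == 0.0:
                continue
            ve_interval = (schedule.ve_interval_active_oxytocin_h if oxy_monitoring
                           else schedule.ve_interval_active_h)
            n_ve = 1 + np.floor((s1_h + s2_h) / ve_interval)
            n_vsm = (np.floor(pre_h / schedule.vsm_interval_pre_active_h)
                     + np.floor(s1_h / schedule.vsm_interval_stage1_h)
                     + np.floor(s2_h / schedule.vsm_interval_stage2_h))
            w = atoms * weight
            minutes["vaginal_examination"] += float(np.sum(w * n_ve)) * schedule.ve_duration_min
            minutes["vital_signs_monitoring"] += float(np.sum(w * n_vsm)) * schedule.vsm_duration_min
            if oxy_setup:
                minutes["oxytocin_setup"] += (
                    float(np.sum(w)) * schedule.oxytocin_setup_midwives
                    * schedule.oxytocin_setup_min_per_midwife
                )
        bed = float(np.sum(atoms * (t + 0.5)))
        bed_by_parity[tr.profile.parity] = bed_by_parity.get(tr.profile.parity, 0.0) + bed
        bed_total += bed
        stay_weighted += tr.n_women * tr.profile.inpatient_stay_h
    return ResourceResult(
        arm=arms.pop(),
        n_women=n_total,
        minutes_by_activity=minutes,
        shift_length_h=staffing.shift_length_h,
        bed_hours=bed_total,
        bed_hours_by_parity=bed_by_parity,
        mean_bed_hours_per_induction=bed_total / n_total,
        mean_pathway_bed_hours_per_induction=(bed_total + stay_weighted) / n_total,
    )


def bed_occupancy(traces: Sequence[CohortTrace]) -> dict[str, float]:
    """Labour-suite bed occupancy (induction through delivery) for one arm."""
    hours = 0.0
    for tr in traces:
        t = np.arange(tr.horizon)
        hours += float(np.sum(tr.atoms_all * (t + 0.5)))
    return {"bed_hours": hours, "bed_days": round(hours / 24.0)}


def capacity_gain(bed_hours_saved: float, mean_bed_hours_per_mvi_induction: float) -> int:
    """Additional inductions per year accommodated by the saved bed hours."""
    if mean_bed_hours_per_mvi_induction <= 0:
        raise ConfigurationError("mean bed-hours per induction must be > 0")
    if bed_hours_saved < 0:
        raise ConfigurationError("bed_hours_saved must be >= 0")
    return math.floor(bed_hours_saved / mean_bed_hours_per_mvi_induction)


def births_per_midwife_adjusted(current_ratio: float,
                                fractional_occupancy_reduction: float) -> float:
    """Births-per-midwife ratio after freeing occupancy, to one decimal."""
    if current_ratio <= 0:
        raise ConfigurationError("current_ratio must be > 0")
    if not 0.0 <= fractional_occupancy_reduction < 1.0:
        raise ConfigurationError("occupancy reduction must lie in [0, 1)")
    return round(current_ratio * (1.0 - fractional_occupancy_reduction), 1)


@dataclass
class ResourceComparison:
    """Paired DVI-vs-MVI resource outcomes."""

    dvi: ResourceResult
    mvi: ResourceResult
    shifts_saved: float
    shifts_saved_by_activity: dict[str, float]
    shift_reduction: float
    bed_hours_saved: float
    bed_hours_saved_by_parity: dict[str, float]
    bed_days_saved: int
    occupancy_reduction: float
    additional_inductions_capacity: int
    births_per_midwife_adjusted: float

    def as_dict(self) -> dict:
        return {
            "shifts": {"DVI": self.dvi.total_shifts, "MVI": self.mvi.total_shifts,
                       "saved": self.shifts_saved,
                       "reduction_pct": 100.0 * self.shift_reduction,
                       "by_activity_saved": self.shifts_saved_by_activity,
                       "by_activity_dvi": self.dvi.shifts_by_activity,
                       "by_activity_mvi": self.mvi.shifts_by_activity},
            "bed": {"hours_saved": self.bed_hours_saved,
                    "days_saved": self.bed_days_saved,
                    "hours_saved_by_parity": self.bed_hours_saved_by_parity,
                    "occupancy_reduction_pct": 100.0 * self.occupancy_reduction},
            "capacity": {"additional_inductions": self.additional_inductions_capacity},
            "births_per_midwife": {"current": None,
                                   "adjusted": self.births_per_midwife_adjusted},
            "shift_length_h": self.dvi.shift_length_h,
        }


def compare_resources(dvi: ResourceResult, mvi: ResourceResult,
                      staffing: StaffingModel) -> ResourceComparison:
    """Derive the headline resource comparison from per-arm results."""
    shifts_saved = dvi.total_shifts - mvi.total_shifts
    by_activity = {a: dvi.shifts_by_activity[a] - mvi.shifts_by_activity[a]
                   for a in ACTIVITIES}
    bed_saved = dvi.bed_hours - mvi.bed_hours
    by_parity = {p: dvi.bed_hours_by_parity[p] - mvi.bed_hours_by_parity.get(p, 0.0)
                 for p in dvi.bed_hours_by_parity}
    occupancy_reduction = bed_saved / dvi.bed_hours if dvi.bed_hours > 0 else 0.0
    cap = capacity_gain(max(bed_saved, 0.0), mvi.mean_pathway_bed_hours_per_induction)
    return ResourceComparison(
        dvi=dvi, mvi=mvi,
        shifts_saved=shifts_saved,
        shifts_saved_by_activity=by_activity,
        shift_reduction=shifts_saved / dvi.total_shifts if dvi.total_shifts > 0 else 0.0,
        bed_hours_saved=bed_saved,
        bed_hours_saved_by_parity=by_parity,
        bed_days_saved=round(bed_saved / 24.0),
        occupancy_reduction=occupancy_reduction,
        additional_inductions_capacity=cap,
        births_per_midwife_adjusted=births_per_midwife_adjusted(
            staffing.current_births_per_midwife, max(occupancy_reduction, 0.0)),
    )
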