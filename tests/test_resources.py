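"""Workload accounting: event conventions, linearity, capacity arithmetic."""

import numpy as np
import pytest

from inductsim import (
    ConfigurationError,
    ParametricCurve,
    ResourceSchedule,
    StaffingModel,
    StratumProfile,
    aggregate_workload,
    bed_occupancy,
    births_per_midwife_adjusted,
    capacity_gain,
    midwife_minutes_for_pathway,
    run_cohort,
)

SCHEDULE = ResourceSchedule()
STAFFING = StaffingModel()


def brute_force_minutes(pre, a1, a2, oxytocin, schedule):
    """Hour-by-hour event enumeration under the completed-interval rule."""
    def events(duration, interval):
        count, t = 0, interval
        while t <= duration + 1e-12:
            count += 1
            t += interval
        return count

    ve_int = (schedule.ve_interval_active_oxytocin_h if oxytocin
              else schedule.ve_interval_active_h)
    n_ve = 1 + events(a1 + a2, ve_int)
    n_vsm = (events(pre, schedule.vsm_interval_pre_active_h)
             + events(a1, schedule.vsm_interval_stage1_h)
             + events(a2, schedule.vsm_interval_stage2_h))
    setup = 20.0 if oxytocin else 0.0
    return {"vaginal_examination": n_ve * schedule.ve_duration_min,
            "vital_signs_monitoring": n_vsm * schedule.vsm_duration_min,
            "oxytocin_setup": setup}


def test_worked_pathway_example():
    """8 h pre-active + 4 h first stage + 1 h second stage, no oxytocin:
    2 examinations (20 min) and 4 observations (12 min)."""
    m = midwife_minutes_for_pathway(8, 4, 1, False, SCHEDULE)
    assert m["vaginal_examination"] == 20.0
    assert m["vital_signs_monitoring"] == 12.0
    assert m["oxytocin_setup"] == 0.0
    assert sum(m.values()) == 32.0


def test_zero_length_pathway_still_gets_entry_examination():
    m = midwife_minutes_for_pathway(0, 0, 0, False, SCHEDULE)
    assert sum(m.values()) == 10.0


def test_oxytocin_pathway_strictly_costlier():
    base = sum(midwife_minutes_for_pathway(8, 4, 1, False, SCHEDULE).values())
    oxy = sum(midwife_minutes_for_pathway(8, 4, 1, True, SCHEDULE).values())
    assert oxy > base
    # the set-up involves two midwives at 10 minutes each
    assert midwife_minutes_for_pathway(8, 4, 1, True, SCHEDULE)["oxytocin_setup"] == 20.0


@pytest.mark.parametrize("seed", range(5))
def test_closed_form_counts_equal_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        pre = float(rng.integers(0, 40))
        a1 = float(rng.integers(0, 5))
        a2 = float(rng.integers(0, 2))
        oxy = bool(rng.integers(0, 2))
        got = midwife_minutes_for_pathway(pre, a1, a2, oxy, SCHEDULE)
        assert got == brute_force_minutes(pre, a1, a2, oxy, SCHEDULE)


def test_negative_duration_rejected():
    with pytest.raises(ConfigurationError):
        midwife_minutes_for_pathway(-1, 0, 0, False, SCHEDULE)


def _profile(n, lam=0.08, oxy=0.5):
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 1.0 / lam}, 1.0)
    return StratumProfile("DVI", "parous", n, curve, None, oxy)


def test_workload_linear_in_cohort_size():
    tr1 = run_cohort(_profile(500.0), horizon=150)
    tr2 = run_cohort(_profile(1000.0), horizon=150)
    r1 = aggregate_workload([tr1], SCHEDULE, STAFFING)
    r2 = aggregate_workload([tr2], SCHEDULE, STAFFING)
    for act in r1.minutes_by_activity:
        assert r2.minutes_by_activity[act] == pytest.approx(
            2.0 * r1.minutes_by_activity[act], rel=1e-12)
    assert r2.total_shifts == pytest.approx(2.0 * r1.total_shifts, rel=1e-12)
    assert r2.bed_hours == pytest.approx(2.0 * r1.bed_hours, rel=1e-12)


def test_per_activity_shifts_sum_to_total(fitted):
    from inductsim.pipeline import _schedule, _staffing
    r = aggregate_workload(fitted.traces["DVI"], _schedule(fitted.config),
                           _staffing(fitted.config))
    assert sum(r.shifts_by_activity.values()) == pytest.approx(r.total_shifts, rel=1e-12)


def test_workload_monotone_in_schedule_parameters(fitted):
    """Longer tasks and tighter intervals never reduce workload."""
    from dataclasses import replace
    from inductsim.pipeline import _schedule, _staffing
    sched, staff = _schedule(fitted.config), _staffing(fitted.config)
    base = aggregate_workload(fitted.traces["DVI"], sched, staff).total_minutes
    for change in ({"ve_duration_min": 12.0}, {"vsm_duration_min": 5.0},
                   {"oxytocin_setup_min_per_midwife": 15.0},
                   {"ve_interval_active_h": 2.0, "ve_interval_active_oxytocin_h": 1.5},
                   {"vsm_interval_pre_active_h": 2.0}):
        perturbed = aggregate_workload(fitted.traces["DVI"],
                                       replace(sched, **change), staff).total_minutes
        assert perturbed >= base


def test_bed_day_rounding_single_woman():
    """One woman occupying a bed for ~24 h counts as one bed day."""
    curve = ParametricCurve("piecewise_exponential",
                            {"knots": (23.0, 24.0), "rates": (0.0, 1e3, 1e3)}, 1.0)
    prof = StratumProfile("DVI", "parous", 1.0, curve, None, 0.0)
    occ = bed_occupancy([run_cohort(prof, horizon=60)])
    assert occ["bed_hours"] == pytest.approx(23.5, abs=1e-6)
    assert occ["bed_days"] == 1


def test_parity_bed_savings_are_additive(fitted):
    r = fitted.resources
    assert sum(r.bed_hours_saved_by_parity.values()) == pytest.approx(
        r.bed_hours_saved, rel=1e-12)


def test_capacity_gain_arithmetic():
    assert capacity_gain(0.0, 25.0) == 0
    assert capacity_gain(100.0, 25.0) == 4
    assert capacity_gain(100.0, 26.0) == 3  # floor, not round
    with pytest.raises(ConfigurationError):
        capacity_gain(100.0, 0.0)


def test_births_per_midwife_adjustment():
    assert births_per_midwife_adjusted(33.0, 0.0) == 33.0
    assert births_per_midwife_adjusted(33.0, 0.274) == 24.0
    assert births_per_midwife_adjusted(30.0, 0.5) == 15.0
    with pytest.raises(ConfigurationError):
        births_per_midwife_adjusted(30.0, 1.0)


def test_invalid_schedule_rejected():
    with pytest.raises(ConfigurationError):
        ResourceSchedule(ve_duration_min=0.0)
    with pytest.raises(ConfigurationError):
        ResourceSchedule(vsm_interval_stage2_h=-1.0)
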