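"""Model / Results front-end.

`LabourInductionModel` bundles the validated configuration; `fit()`
performs curve calibration and propagates both arms through the hourly
Markov structure, returning a `LabourInductionResults` object that
carries the calibrated curves, the traces, the clinical and resource
comparisons and the adverse-event accounting, with `summary()`,
sensitivity/scenario methods and seeded micro-simulation hanging off it.

Example
-------
>>> from inductsim import LabourInductionModel
>>> res = LabourInductionModel.basecase().fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import adverse_events as ae
from . import cohort as coh
from . import resources as res
from . import sensitivity as sens
from . import synthetic as syn
from .config import PipelineConfig, load_basecase, load_config
from .pipeline import (
    _base_outputs,
    _schedule,
    _staffing,
    _assumptions,
    run_pipeline,
)

__all__ = ["LabourInductionModel", "LabourInductionResults"]


class LabourInductionModel:
    """Hourly-cycle Markov cohort model of labour induction.

    Parameters
    ----------
    config : PipelineConfig
        Validated configuration (cohort composition, per-stratum
        efficacy anchors, caesarean and oxytocin parameters, AE rates,
        care schedule, staffing).  Use :meth:`basecase` for the
        published inputs.
    """

    def __init__(self, config: PipelineConfig):
        self.config = config

    @classmethod
    def basecase(cls) -> "LabourInductionModel":
        return cls(load_basecase())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabourInductionModel":
        return cls(load_config(path))

    def fit(self) -> "LabourInductionResults":
        """Calibrate curves and run both arms through the Markov engine."""
        curves, profiles, traces, clinical, resources, aes = _base_outputs(self.config)
        return LabourInductionResults(self, curves, profiles, traces,
                                      clinical, resources, aes)


class LabourInductionResults:
    """Fitted results: estimates, comparisons and diagnostics."""

    def __init__(self, model, curves, profiles, traces, clinical, resources, aes):
        self.model = model
        self.config: PipelineConfig = model.config
        self.curves = curves
        self.profiles = profiles
        self.traces = traces
        self.clinical: coh.ComparisonResult = clinical
        self.resources: res.ResourceComparison = resources
        self.adverse_events: ae.AEResult = aes

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        c, r, a = self.clinical, self.resources, self.adverse_events
        cfg = self.config
        lines = [
            "Labour induction cohort model: MVI vs DVI",
            "=" * 58,
            f"Cohort: {cfg.cohort.n_total} inductions "
            f"({cfg.cohort.parous} parous / {cfg.cohort.nulliparous} nulliparous), "
            f"{cfg.cohort.annual_births} annual births",
            f"Curve family: {cfg.calibration.family} "
            f"(tail calibrated to printed means: {cfg.calibration.calibrate_tail_to_mean})",
            "",
            "Clinical effectiveness",
            "-" * 58,
            f"  Mean time to vaginal delivery   DVI {c.dvi.mean_time_to_vd_h:6.1f} h   "
            f"MVI {c.mvi.mean_time_to_vd_h:6.1f} h",
            f"  Hours to VD saved (cohort/yr)   {c.hours_saved_total:8.0f} h "
            f"({100 * c.relative_reduction:.1f} %)",
            f"  Saving per induction            {c.hours_saved_per_induction:8.1f} h",
            f"  VD within 12 h                  DVI {100 * c.dvi.p_vd_within[12]:5.1f} %   "
            f"MVI {100 * c.mvi.p_vd_within[12]:5.1f} %",
            f"  VD within 24 h                  DVI {100 * c.dvi.p_vd_within[24]:5.1f} %   "
            f"MVI {100 * c.mvi.p_vd_within[24]:5.1f} %",
            f"  Prolonged labour (>24 h)        DVI {100 * c.prolonged_dvi:5.1f} %   "
            f"MVI {100 * c.prolonged_mvi:5.1f} %",
            "",
            "Resource use (per year)",
            "-" * 58,
            f"  Midwife shifts ({cfg.staffing.shift_length_h:.0f} h)            "
            f"DVI {r.dvi.total_shifts:6.1f}     MVI {r.mvi.total_shifts:6.1f}   "
            f"saved {r.shifts_saved:5.1f} ({100 * r.shift_reduction:.1f} %)",
            f"  ... oxytocin set-up             DVI {r.dvi.shifts_by_activity['oxytocin_setup']:6.1f}"
            f"     MVI {r.mvi.shifts_by_activity['oxytocin_setup']:6.1f}",
            f"  Suite bed-hours saved           {r.bed_hours_saved:8.0f} h "
            f"({r.bed_days_saved} bed days, {100 * r.occupancy_reduction:.1f} %)",
            f"  Additional inductions/yr        {r.additional_inductions_capacity:8d}",
            f"  Births per midwife              {cfg.staffing.current_births_per_midwife:.1f} "
            f"-> {r.births_per_midwife_adjusted:.1f}",
            "",
            "Treatment-related adverse events",
            "-" * 58,
            f"  Expected events                 DVI {a.total_dvi:6d}     MVI {a.total_mvi:6d}   "
            f"(+{a.per_woman_excess:.2f} per woman, {a.fold_total_from_counts:.1f}-fold)",
        ]
        return "\n".join(lines)

    def assumptions(self) -> dict:
        return _assumptions(self.config)

    def per_parity_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.clinical.per_parity).T

    # -- downstream analyses -------------------------------------------------
    def sensitivity(self, spec: sens.SensitivitySpec | None = None) -> sens.SensitivityGrid:
        if spec is None:
            spec = sens.SensitivitySpec(
                parameters=tuple(self.config.sensitivity.parameters),
                factors=tuple(self.config.sensitivity.factors))
        return sens.run_dsa(self.traces["DVI"], self.traces["MVI"],
                            _schedule(self.config), _staffing(self.config), spec)

    def scenario_continuous_monitoring(self, apply_to_dvi: bool = False) -> res.ResourceComparison:
        return sens.scenario_continuous_monitoring(
            self.traces["DVI"], self.traces["MVI"],
            _schedule(self.config), _staffing(self.config), apply_to_dvi=apply_to_dvi)

    def simulate(self, n_per_stratum: int, seed: int | None = None) -> syn.SyntheticCohort:
        seed = self.config.seed if seed is None else seed
        profiles = [p for arm in ("DVI", "MVI") for p in self.profiles[arm]]
        return syn.sample_cohort(profiles, n_per_stratum, seed)

    def validate(self, n_per_stratum: int = 100_000, seed: int | None = None) -> pd.DataFrame:
        cohort = self.simulate(n_per_stratum, seed)
        traces = [t for arm in ("DVI", "MVI") for t in self.traces[arm]]
        return syn.microsim_vs_cohort(cohort, traces, _schedule(self.config))

    def report(self, mode: str = "base", outdir=None) -> dict:
        return run_pipeline(self.config, mode=mode, outdir=outdir)
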