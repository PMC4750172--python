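"""Stage orchestration: calibrate -> cohort -> resources -> adverse events,
plus the sensitivity, scenario and validation modes, and report assembly.

Every numeric in the emitted report bundle is a stage output; the bundle
also carries an assumptions appendix echoing each modelling choice in
force (curve family, tail handling, caesarean-timing assumption,
active-labour residency, shift length, postnatal stay, horizon) so that
provenance is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import adverse_events as ae
from . import cohort as coh
from . import curves as crv
from . import resources as res
from . import sensitivity as sens
from . import synthetic as syn
from .config import PipelineConfig
from .errors import ConfigurationError

__all__ = ["calibrate_from_config", "build_profiles", "run_pipeline", "write_report"]

log = logging.getLogger("inductsim")

ARMS = ("DVI", "MVI")
PARITIES = ("parous", "nulliparous")


def calibrate_from_config(config: PipelineConfig) -> dict[str, dict[str, crv.ParametricCurve]]:
    """Per-arm, per-parity vaginal-delivery curves from the config anchors."""
    sizes = config.stratum_sizes()
    out: dict[str, dict[str, crv.ParametricCurve]] = {}
    for arm in ARMS:
        blk = config.arms[arm]
        anchors = {
            parity: crv.SummaryAnchors(
                arm=arm, parity=parity,
                p_vd_12h=blk.anchors[parity].p_vd_12h,
                p_vd_24h=blk.anchors[parity].p_vd_24h,
                cs_total=blk.cs_total,
                median_vd_h=blk.median_vd_h, mean_vd_h=blk.mean_vd_h,
            )
            for parity in PARITIES
        }
        mean_target = blk.mean_vd_h if config.calibration.calibrate_tail_to_mean else None
        out[arm] = crv.calibrate_strata(
            anchors, weights={p: float(sizes[p]) for p in PARITIES},
            family=config.calibration.family, arm_mean_vd_h=mean_target,
        )
        log.info("calibrated %s curves (%s): %s", arm, config.calibration.family,
                 {p: dict(c.params) for p, c in out[arm].items()})
    return out


def build_profiles(config: PipelineConfig,
                   curves: Mapping[str, Mapping[str, crv.ParametricCurve]] | None = None,
                   ) -> dict[str, list[coh.StratumProfile]]:
    """Stratum profiles per arm, with same-shape caesarean curves."""
    curves = curves or calibrate_from_config(config)
    sizes = config.stratum_sizes()
    profiles: dict[str, list[coh.StratumProfile]] = {}
    for arm in ARMS:
        blk = config.arms[arm]
        profiles[arm] = [
            coh.StratumProfile(
                arm=arm, parity=parity, n_women=float(sizes[parity]),
                vd_curve=curves[arm][parity],
                cs_curve=coh.caesarean_curve_like(curves[arm][parity], blk.cs_total),
                oxytocin_prob=blk.oxytocin_prob,
                oxytocin_duration_h=blk.oxytocin_duration_h,
                inpatient_stay_h=config.inpatient_stay_h,
            )
            for parity in PARITIES
        ]
    return profiles


def _schedule(config: PipelineConfig) -> res.ResourceSchedule:
    return res.ResourceSchedule(**config.schedule.model_dump())


def _staffing(config: PipelineConfig) -> res.StaffingModel:
    return res.StaffingModel(**config.staffing.model_dump())


def _assumptions(config: PipelineConfig) -> dict:
    return {
        "curve_family": config.calibration.family,
        "tail_calibrated_to_printed_arm_means": config.calibration.calibrate_tail_to_mean,
        "caesarean_timing": "same shape as the stratum's vaginal-delivery curve, "
                            "rescaled to the caesarean mass (no printed anchor)",
        "active_labour_residency_h": {
            "first_stage": config.calibration.active_labour_first_stage_h,
            "second_stage": config.calibration.active_labour_second_stage_h,
        },
        "event_time_convention": "mid-cycle (+0.5 h)",
        "scheduled_event_convention": "completed intervals; admission examination on entry",
        "shift_length_h": config.staffing.shift_length_h,
        "oxytocin_prob": {a: config.arms[a].oxytocin_prob for a in ARMS},
        "oxytocin_duration_h": {a: config.arms[a].oxytocin_duration_h for a in ARMS},
        "inpatient_stay_h": config.inpatient_stay_h,
        "suite_occupancy": "induction through delivery; postnatal stay excluded "
                           "from suite savings, included in the per-induction "
                           "bed footprint used for capacity",
        "horizon_cycles": config.horizon,
        "seed": config.seed,
    }


def _base_outputs(config: PipelineConfig):
    curves = calibrate_from_config(config)
    profiles = build_profiles(config, curves)
    traces = {arm: [coh.run_cohort(p, horizon=config.horizon) for p in profiles[arm]]
              for arm in ARMS}
    clinical = coh.compare_arms(traces["DVI"], traces["MVI"])
    schedule, staffing = _schedule(config), _staffing(config)
    workload = {arm: res.aggregate_workload(traces[arm], schedule, staffing) for arm in ARMS}
    resources = res.compare_resources(workload["DVI"], workload["MVI"], staffing)
    aes = ae.expected_ae_counts(ae.AEProfile(rates=config.ae_rates), config.cohort.n_total)
    return curves, profiles, traces, clinical, resources, aes


def run_pipeline(config: PipelineConfig, mode: str = "base",
                 outdir: str | Path | None = None) -> dict:
    """Execute the pipeline and return (optionally write) a report bundle.

    Modes: ``base`` (clinical + resources + adverse events), ``dsa``
    (adds the deterministic sensitivity grid), ``scenario`` (adds the
    continuous-monitoring scenario), ``validate`` (adds the
    micro-simulation agreement report).
    """
    if mode not in ("base", "dsa", "scenario", "validate"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    curves, profiles, traces, clinical, resources, aes = _base_outputs(config)
    schedule, staffing = _schedule(config), _staffing(config)

    report: dict = {
        "mode": mode,
        "cohort": {
            "n_inductions": config.cohort.n_total,
            "annual_births": config.cohort.annual_births,
            "induced_fraction_pct": round(100.0 * config.cohort.n_total
                                          / config.cohort.annual_births, 1),
            "parous": config.cohort.parous,
            "nulliparous": config.cohort.nulliparous,
            "parous_fraction_pct": round(100.0 * config.cohort.parous
                                         / config.cohort.n_total, 1),
        },
        "calibration": {
            arm: {parity: {"family": c.family, "mass": c.mass,
                           **{k: (list(v) if isinstance(v, (tuple, list)) else v)
                              for k, v in c.params.items()},
                           **crv.curve_summary(c)}
                  for parity, c in curves[arm].items()}
            for arm in ARMS
        },
        "clinical": clinical.as_dict(),
        "resources": resources.as_dict(),
        "adverse_events": aes.as_dict(),
        "assumptions": _assumptions(config),
    }
    report["resources"]["births_per_midwife"]["current"] = staffing.current_births_per_midwife

    if mode == "dsa":
        spec = sens.SensitivitySpec(parameters=tuple(config.sensitivity.parameters),
                                    factors=tuple(config.sensitivity.factors))
        grid = sens.run_dsa(traces["DVI"], traces["MVI"], schedule, staffing, spec)
        report["sensitivity"] = {
            "grid": grid.table.to_dict(orient="records"),
            "worst_case": grid.worst_case().to_dict(),
            "best_case": grid.best_case().to_dict(),
        }
    elif mode == "scenario":
        scen = sens.scenario_continuous_monitoring(traces["DVI"], traces["MVI"],
                                                   schedule, staffing)
        report["scenario_continuous_monitoring"] = scen.as_dict()
    elif mode == "validate":
        n_sim = 100_000
        cohort = syn.sample_cohort([p for arm in ARMS for p in profiles[arm]],
                                   n_per_stratum=n_sim, seed=config.seed)
        agreement = syn.microsim_vs_cohort(
            cohort, [t for arm in ARMS for t in traces[arm]], schedule)
        report["validation"] = {
            "n_per_stratum": n_sim,
            "all_ok": bool((agreement["flag"] == "ok").all()),
            "table": agreement.to_dict(orient="records"),
        }

    if outdir is not None:
        write_report(report, traces, Path(outdir))
    return report


def write_report(report: dict, traces, outdir: Path) -> None:
    """Write the JSON bundle plus CSV side-tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    for arm, arm_traces in traces.items():
        for tr in arm_traces:
            tr.to_csv(outdir / f"trace_{arm}_{tr.profile.parity}.csv")
    cal_rows = []
    for arm, strata in report["calibration"].items():
        for parity, entry in strata.items():
            cal_rows.append({"arm": arm, "parity": parity, **{
                k: (";".join(map(str, v)) if isinstance(v, list) else v)
                for k, v in entry.items()}})
    pd.DataFrame(cal_rows).to_csv(outdir / "calibrated_curves.csv", index=False)
    if "sensitivity" in report:
        pd.DataFrame(report["sensitivity"]["grid"]).to_csv(
            outdir / "sensitivity_grid.csv", index=False)
    if "validation" in report:
        pd.DataFrame(report["validation"]["table"]).to_csv(
            outdir / "validation.csv", index=False)
    log.info("report written to %s", outdir)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
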