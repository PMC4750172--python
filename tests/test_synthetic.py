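"""Synthetic cohorts, competing-risk estimation and the agreement harness."""

import numpy as np
import pandas as pd
import pytest

from inductsim import (
    ConfigurationError,
    ParametricCurve,
    StratumProfile,
    caesarean_curve_like,
    fit_curve_to_anchors,
    km_estimate,
    microsim_vs_cohort,
    sample_cohort,
)
from inductsim.curves import SummaryAnchors
from inductsim.pipeline import _schedule


@pytest.fixture(scope="module")
def profiles(fitted):
    return [p for arm in ("DVI", "MVI") for p in fitted.profiles[arm]]


def test_same_seed_reproduces_cohort_exactly(profiles):
    a = sample_cohort(profiles, 2000, seed=42)
    b = sample_cohort(profiles, 2000, seed=42)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    c = sample_cohort(profiles, 2000, seed=43)
    assert not a.frame["time_to_delivery_h"].equals(c.frame["time_to_delivery_h"])


def test_empirical_12h_proportion_within_binomial_error(profiles):
    n = 100_000
    cohort = sample_cohort(profiles, n, seed=7)
    df = cohort.stratum("DVI", "parous")
    p_hat = ((df["outcome"] == "vaginal") & (df["time_to_delivery_h"] < 12.0)).mean()
    p = 0.183
    assert abs(p_hat - p) <= 3.0 * np.sqrt(p * (1 - p) / n)


def test_exponential_sample_mean_within_three_se():
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 10.0}, 1.0)
    prof = StratumProfile("DVI", "parous", 1.0, curve, None, 0.0)
    n = 50_000
    cohort = sample_cohort([prof], n, seed=11)
    t = cohort.frame["time_to_delivery_h"]
    assert abs(t.mean() - 10.0) <= 3.0 * t.std() / np.sqrt(n)


def test_outcome_frequencies_match_masses(profiles):
    cohort = sample_cohort(profiles, 50_000, seed=3)
    for prof in profiles:
        df = cohort.stratum(prof.arm, prof.parity)
        frac_cs = (df["outcome"] == "caesarean").mean()
        assert frac_cs == pytest.approx(prof.cs_curve.mass, abs=0.01)


def test_km_single_woman_steps_to_one():
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 10.0}, 1.0)
    prof = StratumProfile("DVI", "parous", 1.0, curve, None, 0.0)
    cohort = sample_cohort([prof], 1, seed=5)
    cohort.frame.loc[0, "time_to_delivery_h"] = 10.0
    cohort.frame.loc[0, "outcome"] = "vaginal"
    est = km_estimate(cohort, "DVI", "parous")
    assert est["cif_vd"].iloc[-1] == pytest.approx(1.0)
    assert (est.loc[est["time_h"] < 10.0, "cif_vd"] == 0.0).all()


def test_km_all_caesarean_is_identically_zero():
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 10.0}, 0.4)
    prof = StratumProfile("DVI", "parous", 1.0, curve,
                          caesarean_curve_like(curve, 0.6), 0.0)
    cohort = sample_cohort([prof], 500, seed=9)
    cohort.frame["outcome"] = "caesarean"
    est = km_estimate(cohort, "DVI", "parous")
    assert (est["cif_vd"] == 0.0).all()


def test_km_matches_uncensored_counting_estimate(profiles):
    """Without censoring the competing-risk estimator reduces to simple
    event counting; the two routes must coincide."""
    cohort = sample_cohort(profiles, 2000, seed=21)
    arm, parity = "MVI", "parous"
    est = km_estimate(cohort, arm, parity)
    df = cohort.stratum(arm, parity)
    n = len(df)
    for t in (6.0, 12.0, 24.0, 48.0):
        counting = ((df["outcome"] == "vaginal")
                    & (df["time_to_delivery_h"] <= t)).sum() / n
        km_val = est.loc[est["time_h"] <= t, "cif_vd"].max() if \
            (est["time_h"] <= t).any() else 0.0
        assert km_val == pytest.approx(counting, abs=1e-9)


def test_empty_stratum_raises(profiles):
    cohort = sample_cohort(profiles[:1], 10, seed=1)
    with pytest.raises(ConfigurationError):
        km_estimate(cohort, "MVI", "nulliparous")


def test_parameter_recovery_from_km_estimate():
    """Re-fitting a curve to anchors read off a large synthetic cohort's
    estimate recovers the generating parameters within Monte-Carlo error."""
    truth = ParametricCurve("weibull", {"shape": 2.2, "scale": 21.0}, 0.73)
    prof = StratumProfile("DVI", "parous", 1.0, truth,
                          caesarean_curve_like(truth, 0.27), 0.0)
    n = 100_000
    cohort = sample_cohort([prof], n, seed=17)
    est = km_estimate(cohort, "DVI", "parous")

    def cif_at(t):
        sel = est.loc[est["time_h"] <= t, "cif_vd"]
        return float(sel.iloc[-1]) if len(sel) else 0.0

    anchors = SummaryAnchors("DVI", "parous", p_vd_12h=cif_at(12.0),
                             p_vd_24h=cif_at(24.0), cs_total=0.27)
    refit = fit_curve_to_anchors(anchors, "weibull")
    assert refit.params["shape"] == pytest.approx(2.2, rel=0.05)
    assert refit.params["scale"] == pytest.approx(21.0, rel=0.02)


def test_agreement_harness_passes_on_matching_cohort(fitted, profiles):
    cohort = sample_cohort(profiles, 20_000, seed=fitted.config.seed)
    traces = [t for arm in ("DVI", "MVI") for t in fitted.traces[arm]]
    table = microsim_vs_cohort(cohort, traces, _schedule(fitted.config))
    assert (table["flag"] == "ok").all()


def test_agreement_harness_flags_perturbed_cohort(fitted, profiles):
    """A cohort drawn from visibly wrong curves must trip the harness."""
    from dataclasses import replace
    wrong = []
    for p in profiles:
        c = p.vd_curve
        shifted = ParametricCurve(c.family,
                                  {"knots": tuple(c.params["knots"]),
                                   "rates": tuple(1.6 * r for r in c.params["rates"])},
                                  c.mass)
        wrong.append(replace(p, vd_curve=shifted,
                             cs_curve=caesarean_curve_like(shifted, p.cs_curve.mass)))
    cohort = sample_cohort(wrong, 20_000, seed=2)
    # present the mismatched cohort as if it came from the fitted profiles
    cohort.profiles = {(p.arm, p.parity): p
                       for arm in ("DVI", "MVI") for p in fitted.profiles[arm]}
    traces = [t for arm in ("DVI", "MVI") for t in fitted.traces[arm]]
    table = microsim_vs_cohort(cohort, traces, None)
    assert (table["flag"] == "mismatch").any()


def test_small_cohort_marked_underpowered(fitted, profiles):
    cohort = sample_cohort(profiles, 10, seed=1)
    traces = [t for arm in ("DVI", "MVI") for t in fitted.traces[arm]]
    table = microsim_vs_cohort(cohort, traces, None)
    assert (table["flag"] == "underpowered").all()


def test_mismatched_parameters_rejected(fitted, profiles):
    from dataclasses import replace
    cohort = sample_cohort(profiles, 100, seed=1)
    cohort.profiles = {k: replace(v, oxytocin_prob=0.123)
                       for k, v in cohort.profiles.items()}
    traces = [t for arm in ("DVI", "MVI") for t in fitted.traces[arm]]
    with pytest.raises(ConfigurationError):
        microsim_vs_cohort(cohort, traces)
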