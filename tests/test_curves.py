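"""Calibration: curve fitting, hazards, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inductsim import (
    AbsorbedStateError,
    CalibrationInfeasibleError,
    ParametricCurve,
    SummaryAnchors,
    calibrate_strata,
    curve_summary,
    fit_curve_to_anchors,
    hourly_transition_probabilities,
)

STRATUM_ANCHORS = {
    ("DVI", "parous"): (0.183, 0.543, 0.271),
    ("DVI", "nulliparous"): (0.016, 0.131, 0.271),
    ("MVI", "parous"): (0.356, 0.700, 0.260),
    ("MVI", "nulliparous"): (0.059, 0.271, 0.260),
}


def make_anchors(arm="DVI", parity="parous"):
    p12, p24, cs = STRATUM_ANCHORS[(arm, parity)]
    return SummaryAnchors(arm=arm, parity=parity, p_vd_12h=p12, p_vd_24h=p24,
                          cs_total=cs)


def test_fit_recovers_known_weibull():
    """Anchors generated from a known curve give back its parameters."""
    truth = ParametricCurve("weibull", {"shape": 2.0, "scale": 20.0}, 1.0)
    anchors = SummaryAnchors("DVI", "parous",
                             p_vd_12h=float(truth.cdf(12.0)),
                             p_vd_24h=float(truth.cdf(24.0)),
                             cs_total=0.0)
    fitted = fit_curve_to_anchors(anchors, family="weibull")
    assert fitted.params["shape"] == pytest.approx(2.0, abs=1e-6)
    assert fitted.params["scale"] == pytest.approx(20.0, abs=1e-6)


@pytest.mark.parametrize("family", ["weibull", "log_logistic", "piecewise_exponential"])
@pytest.mark.parametrize("stratum", sorted(STRATUM_ANCHORS))
def test_anchor_round_trip(family, stratum):
    """Every calibrated stratum reproduces both printed proportions to 1e-8."""
    anchors = make_anchors(*stratum)
    curve = fit_curve_to_anchors(anchors, family=family)
    assert float(curve.cdf(12.0)) == pytest.approx(anchors.p_vd_12h, abs=1e-8)
    assert float(curve.cdf(24.0)) == pytest.approx(anchors.p_vd_24h, abs=1e-8)
    assert curve.mass == pytest.approx(1.0 - anchors.cs_total)


def test_infeasible_anchors_raise():
    with pytest.raises(CalibrationInfeasibleError):
        SummaryAnchors("DVI", "parous", p_vd_12h=0.6, p_vd_24h=0.5, cs_total=0.1)
    with pytest.raises(CalibrationInfeasibleError):
        # 24-h proportion above the vaginal-delivery plateau
        SummaryAnchors("DVI", "parous", p_vd_12h=0.3, p_vd_24h=0.8, cs_total=0.3)


def test_hourly_probabilities_match_direct_cdf_arithmetic():
    curve = fit_curve_to_anchors(make_anchors(), family="weibull")
    p = hourly_transition_probabilities(curve, horizon=30)
    F = curve.cdf(np.arange(31.0))
    for t in (0, 5, 12, 29):
        assert p[t] == pytest.approx((F[t + 1] - F[t]) / (1 - F[t]), rel=1e-12)


def test_exponential_curve_has_constant_hazard():
    lam = 0.1
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 1.0 / lam}, 1.0)
    p = hourly_transition_probabilities(curve, horizon=50)
    assert np.allclose(p, 1.0 - math.exp(-lam), rtol=1e-12)


def test_subdistribution_hazard_vanishes_at_plateau():
    curve = fit_curve_to_anchors(make_anchors(), family="weibull")
    p = hourly_transition_probabilities(curve, horizon=400)
    assert p[-1] < 1e-6


def test_absorbed_state_error_on_saturated_cdf():
    curve = ParametricCurve("piecewise_exponential",
                            {"knots": (5.0,), "rates": (50.0, 50.0)}, 1.0)
    with pytest.raises(AbsorbedStateError):
        hourly_transition_probabilities(curve, horizon=48)


def test_telescoping_identity_probabilities_recover_cdf():
    """Propagating the hourly probabilities through a shrinking risk set
    recovers F(horizon) (numerical check of the telescoping identity)."""
    for family in ("weibull", "piecewise_exponential"):
        curve = fit_curve_to_anchors(make_anchors("MVI", "nulliparous"), family)
        horizon = 96
        p = hourly_transition_probabilities(curve, horizon)
        at_risk, delivered = 1.0, 0.0
        for pt in p:
            delivered += at_risk * pt
            at_risk *= 1.0 - pt
        assert delivered == pytest.approx(float(curve.cdf(horizon)), abs=1e-9)


def test_curve_summary_exponential_closed_form():
    curve = ParametricCurve("weibull", {"shape": 1.0, "scale": 10.0}, 1.0)
    s = curve_summary(curve)
    assert s["median_h"] == pytest.approx(10 * math.log(2), rel=1e-9)
    assert s["mean_h"] == pytest.approx(10.0, rel=1e-9)


def test_piecewise_mean_matches_quadrature():
    curve = fit_curve_to_anchors(make_anchors(), family="piecewise_exponential")
    from scipy.integrate import quad
    mean_quad, _ = quad(lambda t: 1.0 - curve.conditional_cdf(t), 0, np.inf, limit=200)
    assert curve.mean_h() == pytest.approx(mean_quad, rel=1e-8)


def test_families_agree_at_anchors_only():
    anchors = make_anchors("MVI", "parous")
    weib = fit_curve_to_anchors(anchors, "weibull")
    llog = fit_curve_to_anchors(anchors, "log_logistic")
    for t in (12.0, 24.0):
        assert float(weib.cdf(t)) == pytest.approx(float(llog.cdf(t)), abs=2e-8)
    assert abs(float(weib.cdf(18.0)) - float(llog.cdf(18.0))) > 1e-4
    assert abs(float(weib.cdf(40.0)) - float(llog.cdf(40.0))) > 1e-4


def test_tail_calibration_hits_arm_mean_and_keeps_anchors():
    anchors = {p: make_anchors("DVI", p) for p in ("parous", "nulliparous")}
    weights = {"parous": 741.0, "nulliparous": 656.0}
    target = 25.2
    curves = calibrate_strata(anchors, weights, family="piecewise_exponential",
                              arm_mean_vd_h=target)
    wmean = sum(weights[p] * curves[p].mean_h() for p in curves) / sum(weights.values())
    assert wmean == pytest.approx(target, abs=1e-6)
    for p, c in curves.items():
        assert float(c.cdf(12.0)) == pytest.approx(anchors[p].p_vd_12h, abs=1e-8)
        assert float(c.cdf(24.0)) == pytest.approx(anchors[p].p_vd_24h, abs=1e-8)


def test_tail_calibration_infeasible_mean_raises():
    anchors = {p: make_anchors("DVI", p) for p in ("parous", "nulliparous")}
    with pytest.raises(CalibrationInfeasibleError):
        calibrate_strata(anchors, {"parous": 1.0, "nulliparous": 1.0},
                         family="piecewise_exponential", arm_mean_vd_h=1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    q1=st.floats(0.02, 0.5),
    gap=st.floats(0.05, 0.45),
    cs=st.floats(0.0, 0.4),
    family=st.sampled_from(["weibull", "log_logistic", "piecewise_exponential"]),
)
def test_round_trip_property(q1, gap, cs, family):
    """Any feasible anchor pair is reproduced exactly by any family."""
    mass = 1.0 - cs
    p12 = q1 * mass
    p24 = min(q1 + gap, 0.98) * mass
    anchors = SummaryAnchors("MVI", "parous", p_vd_12h=p12, p_vd_24h=p24, cs_total=cs)
    curve = fit_curve_to_anchors(anchors, family)
    assert float(curve.cdf(12.0)) == pytest.approx(p12, abs=1e-8)
    assert float(curve.cdf(24.0)) == pytest.approx(p24, abs=1e-8)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(q=st.floats(0.001, 0.999),
       family=st.sampled_from(["weibull", "log_logistic", "piecewise_exponential"]))
def test_quantile_inverts_cdf(q, family):
    curve = fit_curve_to_anchors(make_anchors("MVI", "parous"), family)
    t = float(curve.conditional_ppf(q))
    assert float(curve.conditional_cdf(t)) == pytest.approx(q, abs=1e-9)
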