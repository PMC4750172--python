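"""Calibration of time-to-delivery curves from printed summary statistics.

The trial's individual-level Kaplan-Meier curves for time from insert
placement to vaginal delivery are unpublished; what is printed are, per
treatment arm and parity stratum, the proportions of women achieving a
vaginal delivery within 12 h and within 24 h, the overall caesarean rate
per arm, and per-arm mean/median times to vaginal delivery.  This module
turns those anchors into parametric cumulative-incidence curves
("sub-distributions": vaginal delivery in the presence of caesarean
section as a competing outcome, so the curve plateaus below 1) and into
the hourly transition probabilities the Markov engine consumes.

Three families are supported:

``weibull``
    F(t) = mass * (1 - exp(-(t/scale)^shape)); two parameters, exactly
    identified by the two proportion anchors.
``log_logistic``
    F(t) = mass / (1 + (t/scale)^-shape); two parameters, exactly
    identified, heavier tail than the Weibull.
``piecewise_exponential``
    Piecewise-constant hazard on [0, 12), [12, 24), [24, inf).  The two
    segment rates are closed-form from the anchors; the tail rate is free
    and defaults to the second-segment rate.  `calibrate_strata` can
    instead solve the tail rate so the parity-weighted mean time to
    vaginal delivery matches the printed arm-level mean -- the anchors
    alone say nothing about the tail, while the mean is itself a printed
    model parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import (
    AbsorbedStateError,
    CalibrationInfeasibleError,
    CalibrationNumericalError,
)

__all__ = [
    "SummaryAnchors",
    "ParametricCurve",
    "fit_curve_to_anchors",
    "calibrate_strata",
    "hourly_transition_probabilities",
    "curve_summary",
]

ANCHOR_TIMES_H = (12.0, 24.0)

#: bisection bracket and tolerance for the shape parameter, after which
#: the scale is available in closed form at every iterate
_SHAPE_BRACKET = (0.05, 20.0)
_SHAPE_TOL = 1e-10
_MAX_BISECTIONS = 200


@dataclass(frozen=True)
class SummaryAnchors:
    """Printed per-stratum efficacy anchors.

    Parameters
    ----------
    arm : {"DVI", "MVI"}
        Dinoprostone or misoprostol vaginal insert.
    parity : {"parous", "nulliparous"}
    p_vd_12h, p_vd_24h : float
        Proportion of the stratum achieving vaginal delivery within
        12 h / 24 h of insert placement (cumulative incidence, i.e.
        caesareans count in the denominator).
    cs_total : float
        Overall caesarean probability for the arm; the vaginal-delivery
        curve plateaus at ``1 - cs_total``.
    median_vd_h, mean_vd_h : float, optional
        Printed arm-level summaries, carried for reference/tail
        calibration; not required for the two-anchor fit.
    """

    arm: str
    parity: str
    p_vd_12h: float
    p_vd_24h: float
    cs_total: float
    median_vd_h: float | None = None
    mean_vd_h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cs_total < 1.0:
            raise CalibrationInfeasibleError(
                f"{self.arm}/{self.parity}: caesarean rate {self.cs_total} outside [0, 1)"
            )
        mass = 1.0 - self.cs_total
        if not 0.0 <= self.p_vd_12h < self.p_vd_24h:
            raise CalibrationInfeasibleError(
                f"{self.arm}/{self.parity}: anchors must satisfy "
                f"0 <= p12 < p24 (got {self.p_vd_12h}, {self.p_vd_24h})"
            )
        if self.p_vd_24h > mass:
            raise CalibrationInfeasibleError(
                f"{self.arm}/{self.parity}: 24-h proportion {self.p_vd_24h} exceeds "
                f"terminal vaginal-delivery mass {mass:.3f}"
            )

    @property
    def mass(self) -> float:
        return 1.0 - self.cs_total


@dataclass(frozen=True)
class ParametricCurve:
    """A (possibly mass-deficient) cumulative-incidence function over hours.

    ``cdf`` evaluates F(t) = mass * G(t) where G is a proper CDF on
    [0, inf).  ``mass`` is the terminal cumulative incidence in (0, 1].
    """

    family: str
    params: Mapping[str, float | Sequence[float]]
    mass: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mass <= 1.0:
            raise ValueError(f"mass must be in (0, 1], got {self.mass}")
        if self.family in ("weibull", "log_logistic"):
            for name in ("shape", "scale"):
                v = self.params[name]
                if not (np.isfinite(v) and v > 0):
                    raise ValueError(f"{self.family} {name} must be finite and positive")
        elif self.family == "piecewise_exponential":
            knots = np.asarray(self.params["knots"], float)
            rates = np.asarray(self.params["rates"], float)
            if len(rates) != len(knots) + 1:
                raise ValueError("piecewise_exponential needs len(rates) == len(knots) + 1")
            if np.any(np.diff(knots) <= 0) or np.any(knots < 0):
                raise ValueError("knots must be non-negative and strictly increasing")
            if np.any(~np.isfinite(rates)) or np.any(rates < 0) or rates[-1] <= 0:
                raise ValueError("rates must be finite, non-negative, tail rate positive")
        else:
            raise ValueError(f"unknown curve family {self.family!r}")

    # -- conditional (normalised) distribution -------------------------------
    def conditional_cdf(self, t) -> np.ndarray:
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        if self.family == "weibull":
            k, s = self.params["shape"], self.params["scale"]
            return 1.0 - np.exp(-((t / s) ** k))
        if self.family == "log_logistic":
            k, s = self.params["shape"], self.params["scale"]
            with np.errstate(divide="ignore"):
                return np.where(t > 0, 1.0 / (1.0 + (t / s) ** -k), 0.0)
        return 1.0 - np.exp(-self._cumhaz(t))

    def _cumhaz(self, t: np.ndarray) -> np.ndarray:
        knots = np.asarray(self.params["knots"], float)
        rates = np.asarray(self.params["rates"], float)
        edges = np.concatenate([[0.0], knots, [np.inf]])
        out = np.zeros_like(t, dtype=float)
        for lo, hi, r in zip(edges[:-1], edges[1:], rates):
            out += r * np.clip(t - lo, 0.0, hi - lo)
        return out

    def cdf(self, t) -> np.ndarray:
        return self.mass * self.conditional_cdf(t)

    def conditional_ppf(self, q) -> np.ndarray:
        """Quantile of the normalised (conditional on delivery) distribution."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile levels must lie in [0, 1)")
        if self.family == "weibull":
            k, s = self.params["shape"], self.params["scale"]
            return s * (-np.log1p(-q)) ** (1.0 / k)
        if self.family == "log_logistic":
            k, s = self.params["shape"], self.params["scale"]
            with np.errstate(divide="ignore"):
                return np.where(q > 0, s * (q / (1.0 - q)) ** (1.0 / k), 0.0)
        # piecewise exponential: invert the cumulative hazard
        target = -np.log1p(-q)
        knots = np.asarray(self.params["knots"], float)
        rates = np.asarray(self.params["rates"], float)
        seg_len = np.diff(np.concatenate([[0.0], knots]))
        H_knots = np.concatenate([[0.0], np.cumsum(rates[:-1] * seg_len)])
        idx = np.searchsorted(H_knots, np.atleast_1d(target), side="right") - 1
        idx = np.clip(idx, 0, len(rates) - 1)
        lo_edge = np.concatenate([[0.0], knots])[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = lo_edge + (np.atleast_1d(target) - H_knots[idx]) / rates[idx]
        res = np.where(np.atleast_1d(q) == 0.0, 0.0, res)
        return res.reshape(np.shape(q))

    def median_h(self) -> float:
        return float(self.conditional_ppf(0.5))

    def mean_h(self) -> float:
        """Mean hours among those who experience the event."""
        if self.family == "weibull":
            k, s = self.params["shape"], self.params["scale"]
            return s * math.gamma(1.0 + 1.0 / k)
        if self.family == "piecewise_exponential":
            knots = np.asarray(self.params["knots"], float)
            rates = np.asarray(self.params["rates"], float)
            edges = np.concatenate([[0.0], knots])
            seg_len = np.diff(np.concatenate([edges, [np.inf]]))
            surv = 1.0
            total = 0.0
            for r, lo, ln in zip(rates, edges, seg_len):
                if np.isinf(ln):
                    total += surv / r
                elif r == 0.0:
                    total += surv * ln
                else:
                    total += surv * (1.0 - math.exp(-r * ln)) / r
                    surv *= math.exp(-r * ln)
            return total
        k, s = self.params["shape"], self.params["scale"]
        if k > 1.0:
            return s * (math.pi / k) / math.sin(math.pi / k)
        val, _ = integrate.quad(lambda t: 1.0 - self.conditional_cdf(t), 0, np.inf, limit=200)
        return val


def _two_anchor_fit(family: str, t1: float, q1: float, t2: float, q2: float,
                    label: str) -> tuple[float, float]:
    """Solve shape/scale so the conditional CDF passes through both anchors.

    Bisection on the shape over a fixed bracket; the scale is closed-form
    from the first anchor at every iterate.  Deterministic.
    """
    if family == "weibull":
        def scale_from_shape(k: float) -> float:
            return t1 / (-math.log1p(-q1)) ** (1.0 / k)

        def resid(k: float) -> float:
            s = scale_from_shape(k)
            return (1.0 - math.exp(-((t2 / s) ** k))) - q2
    else:  # log_logistic
        def scale_from_shape(k: float) -> float:
            return t1 * (q1 / (1.0 - q1)) ** (-1.0 / k)

        def resid(k: float) -> float:
            s = scale_from_shape(k)
            return 1.0 / (1.0 + (t2 / s) ** -k) - q2

    lo, hi = _SHAPE_BRACKET
    flo, fhi = resid(lo), resid(hi)
    if flo == 0.0:
        return lo, scale_from_shape(lo)
    if fhi == 0.0:
        return hi, scale_from_shape(hi)
    if flo * fhi > 0:
        raise CalibrationNumericalError(
            f"{label}: no {family} shape in [{lo}, {hi}] reproduces the anchors"
        )
    for _ in range(_MAX_BISECTIONS):
        mid = 0.5 * (lo + hi)
        fm = resid(mid)
        if fm == 0.0 or (hi - lo) < _SHAPE_TOL:
            return mid, scale_from_shape(mid)
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    raise CalibrationNumericalError(f"{label}: shape bisection did not converge")


def fit_curve_to_anchors(anchors: SummaryAnchors, family: str = "weibull") -> ParametricCurve:
    """Fit a curve of the given family through the two proportion anchors.

    The anchors are interpreted as cumulative incidence of vaginal
    delivery with caesarean as a competing outcome: the fitted curve
    satisfies ``F(12) = p_vd_12h`` and ``F(24) = p_vd_24h`` to within
    1e-8 and plateaus at ``mass = 1 - cs_total``.
    """
    label = f"{anchors.arm}/{anchors.parity}"
    mass = anchors.mass
    t1, t2 = ANCHOR_TIMES_H
    q1, q2 = anchors.p_vd_12h / mass, anchors.p_vd_24h / mass
    if q2 >= 1.0:
        raise CalibrationInfeasibleError(
            f"{label}: 24-h anchor saturates the sub-distribution mass"
        )
    if family in ("weibull", "log_logistic"):
        shape, scale = _two_anchor_fit(family, t1, q1, t2, q2, label)
        curve = ParametricCurve(family, {"shape": shape, "scale": scale}, mass)
    elif family == "piecewise_exponential":
        r1 = -math.log1p(-q1) / t1
        r2 = -math.log((1.0 - q2) / (1.0 - q1)) / (t2 - t1)
        curve = ParametricCurve(
            "piecewise_exponential",
            {"knots": (t1, t2), "rates": (r1, r2, r2)},
            mass,
        )
    else:
        raise ValueError(f"unknown curve family {family!r}")

    for t_a, p_a in ((t1, anchors.p_vd_12h), (t2, anchors.p_vd_24h)):
        if abs(float(curve.cdf(t_a)) - p_a) > 1e-8:
            raise CalibrationNumericalError(
                f"{label}: fitted {family} misses anchor at {t_a} h"
            )
    return curve


def _with_tail_rate(curve: ParametricCurve, tail_rate: float) -> ParametricCurve:
    rates = list(np.asarray(curve.params["rates"], float))
    rates[-1] = tail_rate
    return ParametricCurve(curve.family,
                           {"knots": tuple(curve.params["knots"]), "rates": tuple(rates)},
                           curve.mass)


def calibrate_strata(
    anchors_by_parity: Mapping[str, SummaryAnchors],
    weights: Mapping[str, float] | None = None,
    family: str = "weibull",
    arm_mean_vd_h: float | None = None,
) -> dict[str, ParametricCurve]:
    """Calibrate all parity strata of one arm, optionally honouring a
    printed arm-level mean time to vaginal delivery.

    With ``family="piecewise_exponential"`` and ``arm_mean_vd_h`` given,
    a single multiplier on the (anchor-unidentified) tail rates is solved
    so the ``weights``-weighted mean among delivered equals the target.
    For two-parameter families the mean target is ignored (the curve is
    already exactly determined).
    """
    curves = {p: fit_curve_to_anchors(a, family) for p, a in anchors_by_parity.items()}
    if arm_mean_vd_h is None or family != "piecewise_exponential":
        return curves
    if weights is None:
        weights = {p: 1.0 for p in curves}
    wtot = sum(weights[p] for p in curves)

    def weighted_mean(theta: float) -> float:
        return sum(
            weights[p]
            * _with_tail_rate(c, theta * float(np.asarray(c.params["rates"])[-1])).mean_h()
            for p, c in curves.items()
        ) / wtot

    lo, hi = 1e-3, 1e3
    if not (weighted_mean(hi) <= arm_mean_vd_h <= weighted_mean(lo)):
        raise CalibrationInfeasibleError(
            f"arm mean {arm_mean_vd_h} h unreachable by tail calibration "
            f"(feasible range [{weighted_mean(hi):.2f}, {weighted_mean(lo):.2f}] h)"
        )
    theta = optimize.brentq(lambda th: weighted_mean(th) - arm_mean_vd_h, lo, hi,
                            xtol=1e-12, rtol=1e-14)
    return {
        p: _with_tail_rate(c, theta * float(np.asarray(c.params["rates"])[-1]))
        for p, c in curves.items()
    }


def hourly_transition_probabilities(curve: ParametricCurve, horizon: int) -> np.ndarray:
    """Per-cycle event probabilities p(t) = (F(t+1) - F(t)) / (1 - F(t)).

    ``p(t)`` is the probability of the event during cycle ``t`` (the hour
    from t to t+1) conditional on not having had it by time t.  For a
    mass-deficient curve p(t) -> 0 as the sub-distribution plateaus.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    grid = np.arange(horizon + 1, dtype=float)
    F = curve.cdf(grid)
    at_risk = 1.0 - F[:-1]
    if np.any(at_risk <= 0.0):
        t_bad = int(np.argmax(at_risk <= 0.0))
        raise AbsorbedStateError(
            f"cumulative incidence reaches 1 at t={t_bad} h; empty risk set"
        )
    p = np.diff(F) / at_risk
    return np.clip(p, 0.0, 1.0 - 1e-15)


def curve_summary(curve: ParametricCurve) -> dict[str, float]:
    """Median and mean hours to the event among those experiencing it."""
    return {"median_h": curve.median_h(), "mean_h": curve.mean_h()}
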