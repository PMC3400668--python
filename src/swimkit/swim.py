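"""Critical swimming speed and the metabolic power curve.

Ucrit follows Brett's incremental-velocity formula

    Ucrit = V + (t / T) * dV

with V the highest speed maintained for a full period, dV the velocity
increment (6 cm s^-1 in the standard protocol), T the period per step
(30 min) and t the time swum at the final, fatiguing speed.

The swimming cost curve is the exponential power model

    MO2(U) = alpha * exp(beta * U)

whose intercept alpha is interpreted as the routine metabolic rate (RMR,
the extrapolated rate at 0 cm s^-1), whose rate constant beta is the
steepness of the cost curve, and whose cost of transport
COT(U) = MO2(U) / U is minimized exactly at the optimal swimming speed
Uopt = 1 / beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

#: cm s^-1 -> km h^-1
_CM_S_TO_KM_H = 0.036


@dataclass
class StepProtocol:
    """Record of one incremental-velocity (Ucrit) trial.

    ``completed_speed`` is the highest speed V swum for the full period;
    ``time_at_final`` the time t (min) swum at the next, fatiguing speed
    (0 <= t < period).  ``step_history`` lists (speed, duration) pairs in
    trial order; all non-final steps last exactly ``period`` minutes.
    """

    delta_v: float  # cm s^-1
    period: float  # min
    completed_speed: float  # cm s^-1
    time_at_final: float  # min
    step_history: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.delta_v <= 0 or self.period <= 0:
            raise InvalidParameterError("delta_v and period must be positive")
        if not 0 <= self.time_at_final < self.period:
            raise InvalidParameterError(
                f"time_at_final must satisfy 0 <= t < T (got t={self.time_at_final}, "
                f"T={self.period}); a full final period means the fish advanced a step"
            )


@dataclass
class PowerCurve:
    """Fitted exponential swim-cost curve MO2 = alpha * exp(beta * U)."""

    alpha: float  # mg O2 kg^-1 h^-1; the RMR
    beta: float  # (cm s^-1)^-1; the steepness
    uopt: float  # cm s^-1; always exactly 1/beta
    residual_sse: float
    n_points: int

    def __call__(self, speed):
        return self.alpha * np.exp(self.beta * np.asarray(speed, dtype=float))


@dataclass
class CotRecord:
    """Cost of transport at one speed, mg O2 kg^-1 km^-1."""

    speed: float  # cm s^-1
    cot: float  # mg O2 kg^-1 km^-1


def compute_ucrit(protocol: StepProtocol) -> float:
    """Brett's critical swimming speed for one trial, cm s^-1."""
    return protocol.completed_speed + (protocol.time_at_final / protocol.period) * protocol.delta_v


def relative_ucrit(ucrit: float, body_length: float) -> float:
    """Ucrit in body lengths per second (cm s^-1 over BL in cm)."""
    if body_length <= 0:
        raise InvalidParameterError("body_length must be positive")
    return ucrit / body_length


def fit_power_curve(
    points: Sequence[tuple[float, float]],
    method: Literal["nls", "loglinear"] = "nls",
) -> PowerCurve:
    """Fit MO2 = alpha * exp(beta * U) to (speed, mo2) pairs.

    The default is nonlinear least squares on the untransformed rates,
    initialized from the log-linear regression of ln(MO2) on speed;
    ``method="loglinear"`` returns the log-linear solution itself.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (speed, mo2) pairs")
    speeds, mo2 = pts[:, 0], pts[:, 1]
    if np.unique(speeds).size < 3:
        raise InsufficientDataError("need at least 3 distinct speeds to fit the power curve")
    if np.any(mo2 <= 0):
        raise InvalidParameterError("all MO2 values must be positive")

    # Log-linear seed: ln(MO2) = ln(alpha) + beta * U.
    b, a = np.polyfit(speeds, np.log(mo2), 1)
    alpha0, beta0 = float(np.exp(a)), float(b)

    if method == "loglinear":
        alpha, beta = alpha0, beta0
    else:
        try:
            (alpha, beta), _ = curve_fit(
                lambda u, al, be: al * np.exp(be * u),
                speeds,
                mo2,
                p0=(alpha0, beta0),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise FitFailureError(f"power-curve fit did not converge: {exc}") from exc
    if alpha <= 0 or beta <= 0:
        raise FitFailureError(
            f"fitted parameters out of range (alpha={alpha:.4g}, beta={beta:.4g}); "
            "MO2 must increase with speed for the power model to apply"
        )
    resid = mo2 - alpha * np.exp(beta * speeds)
    return PowerCurve(
        alpha=float(alpha),
        beta=float(beta),
        uopt=1.0 / float(beta),
        residual_sse=float(resid @ resid),
        n_points=int(pts.shape[0]),
    )


def rmr_from_fit(curve: PowerCurve) -> float:
    """Routine metabolic rate: the fitted curve at 0 cm s^-1 (= alpha)."""
    return curve.alpha


def optimal_speed(curve: PowerCurve) -> float:
    """Optimal swimming speed Uopt = 1/beta, the analytic COT minimizer."""
    if curve.beta <= 0:
        raise InvalidParameterError("optimal speed requires beta > 0")
    return 1.0 / curve.beta


def compute_cot(mo2_std: float, speed: float) -> CotRecord:
    """Cost of transport: oxygen per kilogram per kilometre travelled.

    COT = MO2 / U with U converted from cm s^-1 to km h^-1.
    """
    if speed <= 0:
        raise InvalidParameterError("speed must be positive for a cost of transport")
    return CotRecord(speed=speed, cot=mo2_std / (speed * _CM_S_TO_KM_H))


def per_speed_mo2(
    records,
    how: Literal["mean", "last"] = "mean",
) -> list[tuple[float, float]]:
    """Collapse QC-passing metabolic records to one (speed, mo2_std) per speed.

    ``how="mean"`` averages all QC-passing records within a speed step,
    ``how="last"`` keeps the final record of each step.
    """
    by_speed: dict[float, list[float]] = {}
    for rec in records:
        if rec.passed_qc:
            by_speed.setdefault(float(rec.speed), []).append(rec.mo2_std)
    out = []
    for speed in sorted(by_speed):
        vals = by_speed[speed]
        out.append((speed, float(np.mean(vals)) if how == "mean" else vals[-1]))
    return out
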