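"""Closed-phase swim-tunnel respirometry.

Turns timestamped dissolved-oxygen depletion traces into quality-controlled,
mass-standardized oxygen-consumption rates (MO2, mg O2 kg^-1 h^-1).

The rate for one closed phase is

    MO2 = slope * (VOL - V_fish) / m

where ``slope`` is the magnitude of the linear O2 depletion (mg L^-1 h^-1)
obtained by ordinary least squares of O2 concentration on time, ``VOL`` the
total respirometer volume (L), ``V_fish`` the volume displaced by the fish (L)
and ``m`` the body mass (kg).  Only slopes whose regression r^2 exceeds a
quality threshold (0.95 by default, strict inequality) enter the analysis,
and rates are adjusted to a 1-kg standard body mass with a mass-scaling
exponent of 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError

#: Allometric mass-scaling exponent b in MO2 ~ m^b used for 1-kg standardization.
MASS_EXPONENT = 0.75

#: Regression-quality threshold: slopes with r^2 strictly above this are kept.
R2_MIN = 0.95


@dataclass
class O2Trace:
    """Dissolved-oxygen series from one closed respirometry phase.

    Parameters
    ----------
    times : array-like
        Sampling times in minutes, strictly increasing, at least 3 samples.
    o2 : array-like
        Dissolved oxygen concentration, mg L^-1, one value per time point.
    resp_volume : float
        Total respirometer volume VOL, litres.
    fish_mass : float
        Body mass m of the fish, kilograms.
    fish_volume : float, optional
        Volume displaced by the fish, litres.  Defaults to ``fish_mass``
        numerically (neutral buoyancy, 1.0 kg L^-1).
    speed : float, optional
        Water velocity (cm s^-1) during the phase, carried as metadata.
    """

    times: np.ndarray
    o2: np.ndarray
    resp_volume: float
    fish_mass: float
    fish_volume: float | None = None
    speed: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.o2.shape:
            raise InvalidParameterError("times and o2 must be 1-D arrays of equal length")
        if self.times.size < 3:
            raise InsufficientDataError("an O2 trace needs at least 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.o2)):
            raise InvalidParameterError("times and o2 must be finite")
        if self.fish_mass <= 0:
            raise InvalidParameterError("fish_mass must be positive")
        if self.fish_volume is None:
            self.fish_volume = float(self.fish_mass)  # neutral buoyancy default
        if self.fish_volume <= 0 or self.resp_volume <= self.fish_volume:
            raise InvalidParameterError(
                "need resp_volume > fish_volume > 0 "
                f"(got VOL={self.resp_volume}, fish={self.fish_volume})"
            )

    @property
    def effective_volume(self) -> float:
        """Water volume actually holding oxygen: VOL minus the fish, litres."""
        return float(self.resp_volume - self.fish_volume)


@dataclass
class MetabolicRecord:
    """One quality-annotated metabolic measurement at a given swimming speed."""

    speed: float  # cm s^-1
    slope: float  # mg L^-1 h^-1, depletion magnitude (>= 0 for physical traces)
    r2: float  # squared correlation of the O2-on-time regression; NaN if undefined
    mo2: float  # mg O2 kg^-1 h^-1
    mo2_std: float  # 1-kg standardized rate, mg O2 kg^-1 h^-1
    passed_qc: bool = field(default=False)


def estimate_slope(trace: O2Trace) -> tuple[float, float]:
    """Least-squares O2 depletion slope of a trace.

    Returns ``(slope, r2)`` where ``slope`` is the depletion magnitude in
    mg L^-1 h^-1 (positive when oxygen decreases; negative values indicate a
    non-physical rising trace and are left signed so QC can reject them) and
    ``r2`` the squared correlation coefficient of the regression (NaN when the
    O2 values have no variance).
    """
    t = trace.times
    y = trace.o2
    if np.var(t) == 0:
        raise DegenerateInputError("zero time variance in trace")
    # OLS of o2 (mg/L) on time (min); convert to per-hour.
    tc = t - t.mean()
    yc = y - y.mean()
    raw_per_min = float(tc @ yc / (tc @ tc))
    ss_tot = float(yc @ yc)
    if ss_tot == 0.0:
        return 0.0, float("nan")
    ss_res = ss_tot - raw_per_min**2 * float(tc @ tc)
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return -raw_per_min * 60.0, r2


def compute_mo2(slope: float, trace: O2Trace) -> float:
    """Mass-specific oxygen consumption, mg O2 kg^-1 h^-1.

    ``slope`` is the depletion magnitude in mg L^-1 h^-1.
    """
    veff = trace.effective_volume
    if veff <= 0:
        raise InvalidParameterError("effective respirometer volume must be positive")
    return slope * veff / trace.fish_mass


def standardize_mass(mo2: float, mass: float, exponent: float = MASS_EXPONENT) -> float:
    """Adjust a per-kg rate to a 1-kg standard body mass.

    Uses the per-kg convention MO2_std = MO2 * m^(1-b) with b the allometric
    exponent (0.75 by default), so smaller fish map to smaller standardized
    per-kg rates.
    """
    if mass <= 0:
        raise InvalidParameterError("mass must be positive")
    return mo2 * mass ** (1.0 - exponent)


def analyze_trace(
    trace: O2Trace, r2_min: float = R2_MIN, mass_exponent: float = MASS_EXPONENT
) -> MetabolicRecord:
    """Full per-trace pipeline: slope, QC flag, MO2 and 1-kg standardization.

    A record passes QC when r^2 > ``r2_min`` (strict) and the raw regression
    slope is physically sensible (oxygen not increasing).
    """
    slope, r2 = estimate_slope(trace)
    physical = slope >= 0
    mo2 = compute_mo2(max(slope, 0.0), trace)
    record = MetabolicRecord(
        speed=trace.speed if trace.speed is not None else float("nan"),
        slope=slope,
        r2=r2,
        mo2=mo2,
        mo2_std=standardize_mass(mo2, trace.fish_mass, mass_exponent),
        passed_qc=bool(physical and np.isfinite(r2) and r2 > r2_min),
    )
    return record


def qc_filter(records: Sequence[MetabolicRecord], r2_min: float = R2_MIN) -> list[MetabolicRecord]:
    """Keep records with r^2 strictly above the threshold and a physical slope.

    ``passed_qc`` is set on every input record; order is preserved in the
    returned (filtered) list.  Idempotent.
    """
    kept = []
    for rec in records:
        ok = bool(np.isfinite(rec.r2) and rec.r2 > r2_min and rec.slope >= 0)
        rec.passed_qc = ok
        if ok:
            kept.append(rec)
    return kept


def extract_mmr(records: Sequence[MetabolicRecord], r2_min: float = R2_MIN) -> float:
    """Maximum metabolic rate: the largest QC-passing standardized MO2.

    Records that fail QC never contribute, even if numerically largest.
    """
    passing = qc_filter(list(records), r2_min)
    if not passing:
        raise InsufficientDataError("no QC-passing records to take a maximum over")
    return max(rec.mo2_std for rec in passing)
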