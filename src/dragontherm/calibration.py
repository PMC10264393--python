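"""Transmitter and temperature-scale calibrations.

Temperature-sensitive transmitters report a pulse rate (beats/min) that maps
to temperature through a per-transmitter quadratic fitted to water-bath
calibration points.  Separate linear calibrations relate transmitter
temperature to skin, body, and ambient-logger temperatures; the published
lines (e.g. T_body = 1.063·T_trans − 3.20) are instances of
:class:`LinearCalibration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "LinearCalibration",
    "fit_pulse_quadratic",
    "pulse_to_temperature",
    "fit_linear_calibration",
    "predict_linear",
    "drift_exceeds",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic pulse-rate → temperature map for one transmitter.

    temperature(p) = c0 + c1·p + c2·p².  ``valid_range`` is the temperature
    interval over which the calibration is trusted (the water-bath span);
    ``pulse_range`` the observed pulse span of the fit, over which the curve
    is verified monotone.
    """

    transmitter_id: str
    c0: float
    c1: float
    c2: float
    valid_range: tuple[float, float] = (5.0, 45.0)
    pulse_range: tuple[float, float] = (0.0, 0.0)
    rmse: float = 0.0


@dataclass(frozen=True)
class LinearCalibration:
    """OLS line y = slope·x + intercept between two temperature scales."""

    slope: float
    intercept: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("linear calibration requires n >= 3")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 outside [0, 1]")


def fit_pulse_quadratic(
    pairs,
    transmitter_id: str,
    valid_range: tuple[float, float] = (5.0, 45.0),
) -> CalibrationCurve:
    """Least-squares quadratic through (pulse, temperature) pairs.

    Requires ≥4 pairs spanning ≥10 °C.  The fitted curve must be strictly
    monotone over the observed pulse range — a sign change in the derivative
    signals corrupted calibration data and raises.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (pulse, temperature)")
    pulse, temp = arr[:, 0], arr[:, 1]
    if len(pulse) < 4:
        raise ValueError("need at least 4 calibration pairs")
    if np.ptp(temp) < 10.0:
        raise ValueError("calibration pairs must span at least 10 °C")
    c2, c1, c0 = np.polyfit(pulse, temp, 2)
    fitted = c0 + c1 * pulse + c2 * pulse**2
    rmse = float(np.sqrt(np.mean((temp - fitted) ** 2)))
    lo, hi = float(pulse.min()), float(pulse.max())
    # derivative c1 + 2 c2 p is linear: monotone iff same sign at both ends
    d_lo, d_hi = c1 + 2 * c2 * lo, c1 + 2 * c2 * hi
    if d_lo * d_hi <= 0:
        raise ValueError(
            f"transmitter {transmitter_id}: fitted quadratic not monotone "
            "over the calibrated pulse range"
        )
    return CalibrationCurve(
        transmitter_id=transmitter_id,
        c0=float(c0), c1=float(c1), c2=float(c2),
        valid_range=valid_range, pulse_range=(lo, hi), rmse=rmse,
    )


def pulse_to_temperature(curve: CalibrationCurve, pulse, with_flag: bool = False):
    """Evaluate the calibration curve; optionally flag out-of-range values.

    Values mapping outside ``curve.valid_range`` are returned as-is; with
    ``with_flag=True`` a boolean out-of-range marker accompanies them.
    """
    p = np.asarray(pulse, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pulse rate must be finite")
    t = curve.c0 + curve.c1 * p + curve.c2 * p**2
    if np.ndim(pulse) == 0:
        t = float(t)
    if not with_flag:
        return t
    lo, hi = curve.valid_range
    flag = (np.asarray(t) < lo) | (np.asarray(t) > hi)
    if np.ndim(pulse) == 0:
        flag = bool(flag)
    return t, flag


def fit_linear_calibration(x, y) -> LinearCalibration:
    """Ordinary least squares of y on x between two temperature scales."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # degenerate but well-defined: flat line explains nothing
        return LinearCalibration(slope=0.0, intercept=float(y[0]), r2=0.0, n=len(x))
    res = stats.linregress(x, y)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def predict_linear(cal: LinearCalibration, x):
    """Evaluate a linear calibration at temperature(s) x."""
    x_arr = np.asarray(x, dtype=float)
    y = cal.slope * x_arr + cal.intercept
    return float(y) if np.ndim(x) == 0 else y


def drift_exceeds(
    pre: CalibrationCurve, post: CalibrationCurve, threshold_c: float = 0.5
) -> bool:
    """Compare pre- vs post-deployment curves at the shared pulse midpoint.

    Transmitters whose predicted temperature drifted by more than
    ``threshold_c`` between calibrations should be flagged for exclusion;
    the threshold is a configurable screening choice.
    """
    if threshold_c <= 0:
        raise ValueError("threshold must be positive")
    lo = max(pre.pulse_range[0], post.pulse_range[0])
    hi = min(pre.pulse_range[1], post.pulse_range[1])
    if hi <= lo:
        warnings.warn("pre/post pulse ranges do not overlap; comparing full-range midpoints")
        mid = 0.5 * (np.mean(pre.pulse_range) + np.mean(post.pulse_range))
    else:
        mid = 0.5 * (lo + hi)
    delta = abs(pulse_to_temperature(pre, mid) - pulse_to_temperature(post, mid))
    return bool(delta > threshold_c)
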