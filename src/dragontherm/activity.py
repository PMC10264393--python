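"""Activity classification and the activity–temperature model.

A dragon is scored *inactive* when its transmitter sits below shaded ground
temperature for at least two consecutive slots (cool refuge) or shows
next-to-no variation in temperature (<0.5 °C) or signal strength over at
least three consecutive slots (stationary); it is scored *active* when its
transmitter exceeds both shade and burrow temperature (out in the open).
Run rules take precedence over the instantaneous open-habitat rule; slots
satisfying neither inherit the previous slot's state, with the first slot of
a day defaulting to inactive (animals emerge well after sunrise).

Daily activity proportions feed a quadratic regression on daily maximum air
temperature — the hump-shaped curve whose decline above ~32 °C drives the
energetic-cost hindcast.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .config import PipelineConfig
from .solar import DaylightWindow

__all__ = [
    "ActivityStates",
    "QuadraticActivityModel",
    "classify_activity",
    "daily_activity",
    "wilson_interval",
    "hourly_activity_by_band",
    "fit_activity_quadratic",
    "predict_activity",
]

ACTIVE, INACTIVE = "active", "inactive"


def _segments(idx_ts: pd.Series, slot_minutes: int) -> list[np.ndarray]:
    """Split positional indices into runs of contiguous slots (gaps reset runs)."""
    ts = idx_ts.to_numpy()
    if len(ts) == 0:
        return []
    step = np.timedelta64(slot_minutes, "m")
    breaks = np.nonzero(np.diff(ts) != step)[0] + 1
    return np.split(np.arange(len(ts)), breaks)


def classify_activity(
    matched: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Two-pass active/inactive classification of one dragon-day.

    ``matched`` must hold microhabitat-matched slots in time order with
    columns ``timestamp, t_trans, t_shade, t_burrow`` and (optionally)
    ``signal_strength``.  Pass 1 marks inactive runs — (a) ≥2 consecutive
    slots with t_trans below shade, (b) ≥3 consecutive slots whose t_trans
    range is < 0.5 °C *or* whose signal range is < signal_delta.  Pass 2
    marks remaining slots active where t_trans exceeds both shade and
    burrow; anything left inherits the previous state (first slot:
    inactive).  Returns the frame plus ``state`` and ``rule_fired`` columns.
    """
    required = {"timestamp", "t_trans", "t_shade", "t_burrow"}
    missing = required - set(matched.columns)
    if missing:
        raise ValueError(
            f"matched slots missing columns {sorted(missing)}; run microhabitat "
            "matching first"
        )
    df = matched.reset_index(drop=True).copy()
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError("slots must be in time order")
    n = len(df)
    t = df["t_trans"].to_numpy(dtype=float)
    shade = df["t_shade"].to_numpy(dtype=float)
    burrow = df["t_burrow"].to_numpy(dtype=float)
    signal = (
        df["signal_strength"].to_numpy(dtype=float)
        if "signal_strength" in df.columns
        else None
    )

    state = np.array([None] * n, dtype=object)
    rule = np.array([None] * n, dtype=object)

    for seg in _segments(df["timestamp"], config.slot_minutes):
        below = t[seg] < shade[seg]
        # (a) cool-refuge runs
        run_start = 0
        for j in range(len(seg) + 1):
            end = j == len(seg)
            if end or not below[j]:
                if j - run_start >= config.refuge_min_slots:
                    sel = seg[run_start:j]
                    state[sel] = INACTIVE
                    rule[sel] = "cool_refuge_run"
                run_start = j + 1
        # (b) stationary runs: any window of stationary_min_slots with a
        # flat temperature or flat signal marks all its member slots
        m = config.stationary_min_slots
        for j in range(len(seg) - m + 1):
            w = seg[j : j + m]
            flat_t = np.ptp(t[w]) < config.stationary_delta_c
            flat_s = signal is not None and np.ptp(signal[w]) < config.signal_delta
            if flat_t or flat_s:
                newly = [k for k in w if state[k] is None]
                state[newly] = INACTIVE
                rule[newly] = "stationary_run"

    prev = INACTIVE  # day-start default: not yet emerged
    for i in range(n):
        if state[i] is None:
            if t[i] > shade[i] and t[i] > burrow[i]:
                state[i] = ACTIVE
                rule[i] = "open_habitat"
            else:
                state[i] = prev
                rule[i] = "carry_forward"
        prev = state[i]

    df["state"] = state
    df["rule_fired"] = rule
    return df


def daily_activity(states: pd.DataFrame) -> float:
    """Proportion of classified daylight slots scored active for one dragon-day."""
    if len(states) == 0:
        raise ValueError("no classified slots")
    return float((states["state"] == ACTIVE).mean())


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form with z the standard-normal quantile of (1+conf)/2; the
    interval is the inversion of the score test and stays within [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = norm.ppf((1.0 + conf) / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    # the closed form hits the boundary exactly at k=0 / k=n; avoid float dust
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return lo, hi


def hourly_activity_by_band(
    states: pd.DataFrame,
    tmax_by_day: Mapping[dt.date, float],
    config: PipelineConfig = PipelineConfig(),
    utc_offset: float = 11.0,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Hour-of-day activity proportions pooled within 5 °C daily-Tmax bands.

    ``states`` holds classified slots across dragons and days with a
    ``date`` column (site-local); each day's maximum air temperature places
    it in a left-closed band of ``band_width_c``.  Returns one row per
    (band, local hour) with the pooled proportion and its Wilson interval.
    """
    df = states.copy()
    if "date" not in df.columns:
        df["date"] = (pd.to_datetime(df["timestamp"]) + pd.Timedelta(hours=utc_offset)).dt.date
    df["tmax"] = df["date"].map(tmax_by_day)
    if df["tmax"].isna().any():
        bad = df.loc[df["tmax"].isna(), "date"].iloc[0]
        raise ValueError(f"no daily Tmax for {bad}")
    width = config.band_width_c
    df["band_lo"] = np.floor(df["tmax"] / width) * width
    df["hour"] = (pd.to_datetime(df["timestamp"]) + pd.Timedelta(hours=utc_offset)).dt.hour
    rows = []
    for (band_lo, hour), grp in df.groupby(["band_lo", "hour"]):
        n = len(grp)
        k = int((grp["state"] == ACTIVE).sum())
        lo, hi = wilson_interval(k, n, conf)
        rows.append((band_lo + width / 2, int(hour), k / n, lo, hi, n))
    return pd.DataFrame(
        rows, columns=["band_mid", "hour", "p_active", "ci_low", "ci_high", "n"]
    )


@dataclass(frozen=True)
class QuadraticActivityModel:
    """proportion = b0 + b1·Tmax + b2·Tmax², clamped to [activity_floor, 1]."""

    b0: float
    b1: float
    b2: float
    r2: float
    p_linear: float
    p_quadratic: float
    tmax_range: tuple[float, float]
    n_days: int
    activity_floor: float = 0.05

    @property
    def vertex(self) -> float:
        """Tmax at the fitted extremum (the activity optimum for b2 < 0)."""
        if self.b2 == 0:
            return float("nan")
        return -self.b1 / (2.0 * self.b2)


def fit_activity_quadratic(
    day_summaries: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    weighted: bool = False,
) -> QuadraticActivityModel:
    """Least-squares quadratic of daily activity proportion on daily Tmax.

    ``day_summaries`` needs columns ``tmax`` and ``prop_active`` (and
    ``n_dragons`` if ``weighted``).  Unweighted by default; the weighted
    variant uses dragons-per-day as weights.  Requires ≥6 days spanning
    ≥10 °C.
    """
    tmax = day_summaries["tmax"].to_numpy(dtype=float)
    prop = day_summaries["prop_active"].to_numpy(dtype=float)
    if len(tmax) < 6:
        raise ValueError("need at least 6 day summaries")
    if np.ptp(tmax) < 10.0:
        raise ValueError("daily Tmax range too narrow (< 10 °C) for a quadratic fit")
    X = sm.add_constant(np.column_stack([tmax, tmax**2]))
    if weighted:
        w = day_summaries["n_dragons"].to_numpy(dtype=float)
        res = sm.WLS(prop, X, weights=w).fit()
    else:
        res = sm.OLS(prop, X).fit()
    b0, b1, b2 = res.params
    with np.errstate(invalid="ignore"):
        r2 = float(res.rsquared)
    return QuadraticActivityModel(
        b0=float(b0), b1=float(b1), b2=float(b2),
        r2=0.0 if np.isnan(r2) else r2,  # constant response explains nothing
        p_linear=float(res.pvalues[1]), p_quadratic=float(res.pvalues[2]),
        tmax_range=(float(tmax.min()), float(tmax.max())),
        n_days=len(tmax),
        activity_floor=config.activity_floor,
    )


def predict_activity(model: QuadraticActivityModel, tmax, with_flag: bool = False):
    """Predicted activity proportion at daily Tmax.

    Inputs outside the fitted Tmax range are clamped to the boundary first
    (no extrapolation of the quadratic); the result is clamped into
    [activity_floor, 1].  ``with_flag=True`` also returns the
    out-of-fitted-range marker.
    """
    x = np.asarray(tmax, dtype=float)
    lo, hi = model.tmax_range
    flag = (x < lo) | (x > hi)
    xc = np.clip(x, lo, hi)
    p = model.b0 + model.b1 * xc + model.b2 * xc**2
    p = np.clip(p, model.activity_floor, 1.0)
    if np.ndim(tmax) == 0:
        p = float(p)
        flag = bool(flag)
    if with_flag:
        return p, flag
    return p
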