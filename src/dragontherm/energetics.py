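"""Metabolic-rate scaling and the energetic-cost statistic.

Resting metabolic rate (RMR, ml O₂ g⁻¹ h⁻¹) scales with temperature as
``RMR = exp(a + b·log T)`` with temperature in °C and natural logs
throughout — at the published coefficients (a = −11.7, b = 2.99) this gives
≈0.22 ml O₂ g⁻¹ h⁻¹ at 30 °C, which is physiologically plausible where a
base-10 reading would not be.  The model is fitted as a linear mixed model
of log RMR on log temperature with a random intercept per individual
(repeat measurements), and evaluated hour-by-hour on transmitter
temperatures to give a daily mean RMR.  The energetic cost of a day is that
mean divided by the proportion of daylight hours active: the energy an
animal must recoup per active hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import PipelineConfig

__all__ = [
    "RMRModel",
    "fit_rmr_model",
    "rmr_at",
    "daily_mean_rmr",
    "energetic_cost",
]

#: temperature span of the respirometry trials; predictions clamp to it
MEASURED_RANGE = (20.0, 38.0)


@dataclass(frozen=True)
class RMRModel:
    """log(RMR) = a + b·log(T °C) with a per-individual random intercept."""

    a: float
    b: float
    sigma_id: float = 0.0
    sigma_resid: float = 0.0
    n_individuals: int = 0
    se_a: float = float("nan")
    se_b: float = float("nan")
    sex_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.b <= 0:
            warnings.warn("fitted RMR slope b <= 0: rate not increasing with temperature")


#: the published fit, usable directly and as a simulation ground truth
PUBLISHED_RMR = RMRModel(a=-11.7, b=2.99)


def fit_rmr_model(data: pd.DataFrame, test_sex: bool = True) -> RMRModel:
    """Fit the random-intercept log–log RMR model.

    ``data`` needs columns ``individual_id, chamber_temp, vo2`` (and ``sex``
    if ``test_sex``).  A single individual, or data with (numerically) zero
    residual variance, falls back to plain OLS with a logged warning — REML
    is undefined there.  The sex term is assessed in a companion fixed-
    effects fit and only its p-value is reported.
    """
    df = data.copy()
    if (df["vo2"] <= 0).any():
        raise ValueError("vo2 must be positive")
    if df["chamber_temp"].nunique() < 3:
        raise ValueError("need at least 3 distinct chamber temperatures")
    df["log_vo2"] = np.log(df["vo2"].astype(float))
    df["log_temp"] = np.log(df["chamber_temp"].astype(float))
    n_ind = df["individual_id"].nunique()

    X = sm.add_constant(df["log_temp"].to_numpy())
    ols = sm.OLS(df["log_vo2"].to_numpy(), X).fit()

    sex_p = float("nan")
    if test_sex and "sex" in df.columns and df["sex"].nunique() > 1:
        sex_fit = smf.ols("log_vo2 ~ log_temp + C(sex)", data=df).fit()
        sex_term = [t for t in sex_fit.pvalues.index if t.startswith("C(sex)")][0]
        sex_p = float(sex_fit.pvalues[sex_term])

    if n_ind < 2 or ols.ssr < 1e-20:
        if n_ind < 2:
            warnings.warn("single individual: mixed model singular, using OLS fallback")
        return RMRModel(
            a=float(ols.params[0]), b=float(ols.params[1]),
            sigma_id=0.0, sigma_resid=float(np.sqrt(max(ols.scale, 0.0))),
            n_individuals=n_ind,
            se_a=float(ols.bse[0]), se_b=float(ols.bse[1]), sex_p=sex_p,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("log_vo2 ~ log_temp", df, groups=df["individual_id"])
        res = md.fit(reml=True)
    return RMRModel(
        a=float(res.params["Intercept"]),
        b=float(res.params["log_temp"]),
        sigma_id=float(np.sqrt(max(float(res.cov_re.iloc[0, 0]), 0.0))),
        sigma_resid=float(np.sqrt(max(res.scale, 0.0))),
        n_individuals=n_ind,
        se_a=float(res.bse["Intercept"]),
        se_b=float(res.bse["log_temp"]),
        sex_p=sex_p,
    )


def rmr_at(model: RMRModel, temp, with_flag: bool = False):
    """Mass-specific RMR at temperature(s) in °C.

    Temperatures are clamped to the measured 20–38 °C chamber range before
    evaluation (no extrapolation of the power law); ``with_flag=True`` also
    returns the clamping marker.  Non-positive temperatures are rejected —
    the log–log model is undefined there.
    """
    t = np.asarray(temp, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 °C for the log-log model")
    lo, hi = MEASURED_RANGE
    flag = (t < lo) | (t > hi)
    tc = np.clip(t, lo, hi)
    v = np.exp(model.a + model.b * np.log(tc))
    if np.ndim(temp) == 0:
        v = float(v)
        flag = bool(flag)
    if with_flag:
        return v, flag
    return v


def daily_mean_rmr(
    slots: pd.DataFrame,
    model: RMRModel,
    utc_offset: float = 11.0,
) -> float:
    """Mean hourly RMR for one dragon-day of daylight transmitter slots.

    Slots are grouped by local clock hour; each hour's mean transmitter
    temperature is converted through the RMR curve and the day's value is
    the mean over hours that have any slots (hours with none are skipped,
    partial hours contribute the slots they have).
    """
    if len(slots) == 0:
        raise ValueError("no daylight slots for this dragon-day")
    ts = pd.to_datetime(slots["timestamp"]) + pd.Timedelta(hours=utc_offset)
    hourly_t = slots.groupby(ts.dt.hour)["t_trans"].mean()
    hourly_rmr = rmr_at(model, hourly_t.to_numpy())
    return float(np.mean(hourly_rmr))


def energetic_cost(
    mean_rmr: float,
    prop_active: float,
    config: PipelineConfig = PipelineConfig(),
    with_flag: bool = False,
):
    """Energetic cost: mean hourly RMR / proportion of daylight hours active.

    The activity proportion is floored at ``config.activity_floor`` so that
    near-zero activity days (where the ratio diverges) stay finite; the
    flag marks days where the floor engaged.
    """
    if mean_rmr <= 0:
        raise ValueError("mean_rmr must be positive")
    if not 0.0 <= prop_active <= 1.0:
        raise ValueError("prop_active must lie in [0, 1]")
    floored = prop_active < config.activity_floor
    cost = mean_rmr / max(prop_active, config.activity_floor)
    if with_flag:
        return cost, floored
    return cost
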