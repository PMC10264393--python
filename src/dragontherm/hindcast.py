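"""Hindcasting activity and energetic cost over a daily-Tmax record.

The fitted activity quadratic and cost LOESS are applied day-by-day to a
multi-decade summer (DJF) daily-maximum temperature record; yearly means
are expressed as anomalies (Tmax) or ratios (activity, cost) relative to
the 1960–1990 baseline, then smoothed with a span-0.3 LOESS.  DJF days are
assigned to their own calendar year by default (Dec 1975 belongs to 1975);
an austral-season option groups December with the following January and
February instead.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .activity import QuadraticActivityModel, predict_activity
from .config import PipelineConfig, SiteGeo
from .smoothing import LoessCurve, fit_loess, predict_loess
from .solar import day_length_hours

__all__ = ["summer_subset", "yearly_anomaly", "project_yearly", "smooth_yearly"]

#: daily activity below this many hours is flagged as severely restricted
RESTRICTION_HOURS = 7.0


def summer_subset(
    climate: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    austral: bool = False,
) -> pd.DataFrame:
    """Summer-month days with a year assignment.

    Keeps days whose month is in ``config.summer_months`` (DJF); the
    ``year`` column is the calendar year, or with ``austral=True`` December
    is pushed into the following year's season.  Missing-Tmax days are kept
    (as NaN) so coverage can be reported; means must exclude them.
    """
    if climate.empty:
        raise ValueError("empty climate record")
    df = climate.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    months = pd.Series([d.month for d in df["date"]], index=df.index)
    df = df[months.isin(config.summer_months)].copy()
    year = np.array([d.year for d in df["date"]])
    if austral:
        dec = np.array([d.month == 12 for d in df["date"]])
        year = year + dec.astype(int)
    df["year"] = year
    return df.reset_index(drop=True)


def yearly_anomaly(
    summer: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Yearly mean summer Tmax as an anomaly from the baseline-period mean.

    The baseline value is the mean over baseline years of the yearly means,
    so anomalies average to zero over the baseline by construction.
    """
    g = summer.groupby("year")["tmax"]
    yearly = g.mean().rename("mean_tmax").reset_index()
    yearly["n_days"] = g.count().to_numpy()
    base = yearly[yearly["year"].isin(config.baseline_years)]
    if base.empty:
        raise ValueError("no baseline years present in the climate record")
    yearly["tmax_anomaly"] = yearly["mean_tmax"] - base["mean_tmax"].mean()
    return yearly


def project_yearly(
    summer: pd.DataFrame,
    activity_model: QuadraticActivityModel,
    cost_curve: LoessCurve,
    config: PipelineConfig = PipelineConfig(),
    site: SiteGeo | None = None,
) -> pd.DataFrame:
    """Yearly activity and cost ratios hindcast from daily summer Tmax.

    Each day's Tmax is pushed through the activity quadratic and the cost
    LOESS (both clamp to their fitted ranges); yearly means are divided by
    the baseline-period mean so baseline ratios average to exactly 1.
    Output columns: ``year, mean_tmax, tmax_anomaly, activity_ratio,
    cost_ratio, n_days, n_missing, low_coverage`` plus, when ``site`` is
    given, ``n_restricted_days`` — days whose predicted active time falls
    short of 7 h (a published population-risk threshold).
    """
    df = summer.dropna(subset=["tmax"]).copy()
    if df.empty:
        raise ValueError("no summer days with Tmax")
    df["p"] = predict_activity(activity_model, df["tmax"].to_numpy())
    df["c"] = predict_loess(cost_curve, df["tmax"].to_numpy())
    if site is not None:
        daylength = np.array([day_length_hours(site.latitude, d) for d in df["date"]])
        df["restricted"] = df["p"] * daylength < RESTRICTION_HOURS

    agg = {"tmax": "mean", "p": "mean", "c": "mean", "date": "count"}
    if site is not None:
        agg["restricted"] = "sum"
    yearly = df.groupby("year").agg(agg).reset_index()
    yearly = yearly.rename(
        columns={"tmax": "mean_tmax", "date": "n_days", "restricted": "n_restricted_days"}
    )

    all_days = summer.groupby("year")["tmax"].size()
    missing = summer.groupby("year")["tmax"].apply(lambda s: int(s.isna().sum()))
    yearly["n_missing"] = yearly["year"].map(missing).fillna(0).astype(int)
    expected = yearly["year"].map(all_days)
    yearly["low_coverage"] = yearly["n_days"] < 0.5 * expected

    base = yearly[yearly["year"].isin(config.baseline_years)]
    if base.empty:
        raise ValueError("no baseline years present in the climate record")
    yearly["tmax_anomaly"] = yearly["mean_tmax"] - base["mean_tmax"].mean()
    yearly["activity_ratio"] = yearly["p"] / base["p"].mean()
    yearly["cost_ratio"] = yearly["c"] / base["c"].mean()
    cols = ["year", "mean_tmax", "tmax_anomaly", "activity_ratio", "cost_ratio",
            "n_days", "n_missing", "low_coverage"]
    if site is not None:
        yearly["n_restricted_days"] = yearly["n_restricted_days"].astype(int)
        cols.append("n_restricted_days")
    return yearly[cols]


def smooth_yearly(
    yearly: pd.DataFrame,
    column: str,
    config: PipelineConfig = PipelineConfig(),
    degree: int = 2,
) -> pd.Series:
    """LOESS-smoothed yearly values (span 0.3) evaluated at each year."""
    if len(yearly) < 10:
        raise ValueError("need at least 10 years to smooth")
    curve = fit_loess(
        yearly["year"].to_numpy(dtype=float),
        yearly[column].to_numpy(dtype=float),
        span=config.loess_span_yearly,
        degree=degree,
    )
    vals = predict_loess(curve, yearly["year"].to_numpy(dtype=float))
    return pd.Series(vals, index=yearly.index, name=f"{column}_smoothed")
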