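"""Seeded generators emulating the field campaign's four input streams.

The generators produce (i) diurnal microclimate series for sun-exposed
ground, shaded ground, and a thermally buffered burrow; (ii) a transmitter
trace for a rule-following shuttling lizard with ground-truth activity
labels; (iii) respirometry draws from the log–log metabolic model with
per-individual random intercepts; (iv) linear-calibration point clouds; and
(v) a multi-decade daily-maximum temperature record with a configurable
late-period warming trend.  Every generator is a pure function of its
parameters and seed.

The lizard agent follows a set-point policy: overnight it rests in a warm
refuge; by day it basks in sun while that keeps its projected temperature
safely below the panting threshold, shuttles between sun and shade around
its preferred temperature when full sun would overheat it, and retreats to
the burrow when even shade exceeds the threshold.  Active slots carry a
small deterministic positional zigzag in temperature and an alternating
signal strength (movement); inactive slots have a constant signal.  This
behavioural variation is part of the policy, not sensor noise, so
"noise-free" runs (sensor_noise_sd = 0) still look like a moving animal.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, SiteGeo
from .limits import ThermalLimits
from .solar import daylight_window

__all__ = [
    "MicroclimateParams",
    "TraceParams",
    "ClimateScenario",
    "gen_microclimate",
    "replicates_from_means",
    "gen_dragon_trace",
    "gen_rmr_dataset",
    "gen_calibration_dataset",
    "gen_climate",
]


# ---------------------------------------------------------------------------
# microclimate


@dataclass(frozen=True)
class MicroclimateParams:
    """Shape parameters of the diurnal microclimate cycles.

    Offsets are relative to the day's maximum air temperature (Stevenson-box
    scale): open sun peaks well above it (copper-pipe loggers averaged a
    59 °C daily maximum on ~30 °C air days), shaded ground a little above,
    and the overnight shade minimum sits ``night_drop`` below.  The burrow
    is an exponentially smoothed, lagged transform of shade confined to a
    band defaulting to the observed 12–36.5 °C envelope.
    """

    sun_peak_offset: float = 25.0
    shade_peak_offset: float = 8.0
    night_drop: float = 16.0
    peak_hour: float = 14.0
    burrow_tau_hours: float = 8.0
    burrow_band: tuple[float, float] = (12.0, 36.5)
    noise_sd: float = 0.5
    n_replicates: int = 3
    replicate_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.burrow_band[0] >= self.burrow_band[1]:
            raise ValueError("burrow band must be a non-degenerate interval")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _local_dates(dates) -> list[dt.date]:
    out = [d.date() if hasattr(d, "date") and not isinstance(d, dt.date) else d for d in dates]
    out = [d if isinstance(d, dt.date) else pd.Timestamp(d).date() for d in out]
    if not out:
        raise ValueError("dates must be non-empty")
    return out


def gen_microclimate(
    site: SiteGeo,
    dates,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    air_tmax: float | Mapping[dt.date, float] = 30.0,
    params: MicroclimateParams = MicroclimateParams(),
) -> pd.DataFrame:
    """Simulate site-slot mean microclimate temperatures on the 10-min grid.

    Returns a frame with columns ``site_id, timestamp, t_sun, t_shade,
    t_burrow`` where ``timestamp`` is the UTC slot start.  ``air_tmax`` sets
    each local day's maximum air temperature (scalar or per-date mapping).
    """
    days = _local_dates(dates)
    rng = np.random.default_rng(seed)
    slot = dt.timedelta(minutes=config.slot_minutes)
    per_day = int(round(24 * 60 / config.slot_minutes))
    offset = dt.timedelta(hours=site.utc_offset)

    amp = (params.shade_peak_offset + params.night_drop) / 2.0
    sun_excess = params.sun_peak_offset - params.shade_peak_offset

    rows_ts, rows_shade, rows_sun = [], [], []
    for day in days:
        a = air_tmax[day] if isinstance(air_tmax, Mapping) else float(air_tmax)
        mean = a + (params.shade_peak_offset - params.night_drop) / 2.0
        win = daylight_window(site, day)
        sr = (win.sunrise + offset - dt.datetime.combine(day, dt.time())).total_seconds() / 3600.0
        ss = (win.sunset + offset - dt.datetime.combine(day, dt.time())).total_seconds() / 3600.0
        local_midnight = dt.datetime.combine(day, dt.time())
        for k in range(per_day):
            t_local = local_midnight + k * slot
            h = k * config.slot_minutes / 60.0
            shade = mean + amp * np.cos(2 * np.pi * (h - params.peak_hour) / 24.0)
            shade += rng.normal(0.0, params.noise_sd)
            if sr < h < ss:
                frac = np.sin(np.pi * (h - sr) / (ss - sr))
            else:
                frac = 0.0
            excess = sun_excess * frac + rng.normal(0.0, params.noise_sd)
            sun = shade + max(excess, 0.0)
            rows_ts.append(t_local - offset)
            rows_shade.append(shade)
            rows_sun.append(sun)

    shade_arr = np.asarray(rows_shade)
    # burrow: first-order low-pass of shade, then confined to the band
    alpha = 1.0 - np.exp(-config.slot_minutes / 60.0 / params.burrow_tau_hours)
    burrow = np.empty_like(shade_arr)
    b = float(np.clip(shade_arr[: min(per_day, len(shade_arr))].mean(), *params.burrow_band))
    for i, s in enumerate(shade_arr):
        b = b + alpha * (s - b)
        burrow[i] = b
    burrow = np.clip(burrow, *params.burrow_band)

    return pd.DataFrame(
        {
            "site_id": site.site_id,
            "timestamp": pd.to_datetime(rows_ts),
            "t_sun": np.asarray(rows_sun),
            "t_shade": shade_arr,
            "t_burrow": burrow,
        }
    )


def replicates_from_means(
    micro: pd.DataFrame,
    params: MicroclimateParams = MicroclimateParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Expand site-slot means into per-logger replicate rows (long format).

    Emits the CSV dialect the microclimate reader consumes: one row per
    (site, slot, habitat, replicate logger) with small inter-logger scatter.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for habitat, col in (("sun", "t_sun"), ("shade", "t_shade"), ("burrow", "t_burrow")):
        for rep in range(1, params.n_replicates + 1):
            noise = rng.normal(0.0, params.replicate_sd, size=len(micro))
            recs.append(
                pd.DataFrame(
                    {
                        "site_id": micro["site_id"],
                        "timestamp": micro["timestamp"],
                        "habitat": habitat,
                        "replicate": rep,
                        "temperature": micro[col].to_numpy() + noise,
                    }
                )
            )
    out = pd.concat(recs, ignore_index=True)
    return out.sort_values(["site_id", "timestamp", "habitat", "replicate"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# lizard agent


@dataclass(frozen=True)
class TraceParams:
    """Behavioural and sensor parameters of the simulated lizard.

    ``setpoint`` is the preferred body temperature targeted while shuttling;
    ``margin`` keeps projected temperatures that far below the skin panting
    threshold.  The transmitter relaxes toward the occupied microhabitat
    temperature with time constant ``tau_minutes`` (transmitters track skin
    and equilibrate within a few minutes).  ``forage_min_sun`` is the
    minimum operative (full-sun) temperature at which foraging is worth
    emerging — below it the animal stays in its refuge, which curtails
    activity on cold days.
    """

    setpoint: float = 35.0
    margin: float = 3.0
    tau_minutes: float = 2.0
    sensor_noise_sd: float = 0.3
    signal_noise_sd: float = 0.3
    emergence_delay_h: float = 1.5
    retreat_advance_h: float = 0.5
    night_refuge_offset: float = 2.0
    forage_min_sun: float = 28.0
    zigzag_amp: float = 0.4
    signal_base: float = 100.0
    signal_jump: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_minutes <= 4.0:
            raise ValueError("tau_minutes must lie in [0, 4] min")
        if self.sensor_noise_sd < 0 or self.signal_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def gen_dragon_trace(
    micro: pd.DataFrame,
    limits: ThermalLimits = ThermalLimits(),
    seed: int = 0,
    site: SiteGeo | None = None,
    params: TraceParams = TraceParams(),
    dragon_id: str = "d01",
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one transmitter trace over a microclimate series.

    Returns ``(telemetry, truth)``: telemetry with columns ``dragon_id,
    site_id, timestamp, t_trans, signal_strength, pulse_rate`` (pulse left
    NaN — the trace is already on the temperature scale) and a parallel
    ground-truth frame with ``state`` (active/inactive) and the occupied
    ``microhabitat``.  Active slots always have an occupied-environment
    temperature strictly above both shade and burrow, so the open-habitat
    classification rule holds on the truth by construction.
    """
    if len(micro) < 2:
        raise ValueError("microclimate series shorter than one slot")
    if site is None:
        site = SiteGeo(str(micro["site_id"].iloc[0]), latitude=-35.34, longitude=149.18)
    micro = micro.sort_values("timestamp").reset_index(drop=True)
    span_h = (micro["timestamp"].iloc[-1] - micro["timestamp"].iloc[0]).total_seconds() / 3600
    if span_h < 24 - config.slot_minutes / 60.0 - 1e-9:
        raise ValueError("microclimate must cover at least one full day")

    rng = np.random.default_rng(seed)
    offset = pd.Timedelta(hours=site.utc_offset)
    windows: dict[dt.date, tuple[pd.Timestamp, pd.Timestamp]] = {}

    env = np.empty(len(micro))
    states: list[str] = []
    habitats: list[str] = []
    guard = 0.5  # occupied-env clearance above max(shade, burrow) while active

    for i, row in enumerate(micro.itertuples(index=False)):
        ts = row.timestamp
        local = ts + offset
        day = local.date()
        if day not in windows:
            w = daylight_window(site, day)
            windows[day] = (pd.Timestamp(w.sunrise), pd.Timestamp(w.sunset))
        sunrise, sunset = windows[day]
        maxsb = max(row.t_shade, row.t_burrow)
        # upward positional zigzag while active: alternating micro-sites make
        # a moving animal's trace vary even without sensor noise, and adding
        # above the clearance floor means clamping can never flatten it
        bump = 2.0 * params.zigzag_amp * (i % 2)
        ceiling = limits.panting_skin - params.margin

        if ts < sunrise or ts > sunset:
            state, habitat = "inactive", "burrow"
            e = row.t_burrow + params.night_refuge_offset
        elif (
            ts < sunrise + pd.Timedelta(hours=params.emergence_delay_h)
            or ts > sunset - pd.Timedelta(hours=params.retreat_advance_h)
        ):
            state, habitat = "inactive", "burrow"
            e = row.t_burrow
        elif row.t_shade >= ceiling:
            # even shade is too close to the panting threshold to shuttle
            state, habitat = "inactive", "burrow"
            e = row.t_burrow
        elif row.t_sun <= maxsb + guard or row.t_sun < params.forage_min_sun:
            state, habitat = "inactive", "burrow"
            e = row.t_burrow
        elif row.t_sun < ceiling:
            state, habitat = "active", "sun"
            e = max(row.t_sun, maxsb + guard) + bump
        else:
            state = "active"
            e = max(min(params.setpoint, ceiling), maxsb + guard) + bump
            habitat = "sun" if abs(e - row.t_sun) < abs(e - row.t_shade) else "shade"
        env[i] = e
        states.append(state)
        habitats.append(habitat)

    decay = 0.0 if params.tau_minutes == 0 else np.exp(-config.slot_minutes / params.tau_minutes)
    t_trans = np.empty_like(env)
    t_trans[0] = env[0]
    for i in range(1, len(env)):
        t_trans[i] = env[i] + (t_trans[i - 1] - env[i]) * decay
    t_trans = t_trans + rng.normal(0.0, params.sensor_noise_sd, size=len(env))

    active = np.array([s == "active" for s in states])
    parity = np.arange(len(env)) % 2
    signal = np.where(
        active, params.signal_base + np.where(parity, 1, -1) * params.signal_jump,
        params.signal_base,
    ).astype(float)
    signal += rng.normal(0.0, params.signal_noise_sd, size=len(env))

    telemetry = pd.DataFrame(
        {
            "dragon_id": dragon_id,
            "site_id": micro["site_id"],
            "timestamp": micro["timestamp"],
            "t_trans": t_trans,
            "signal_strength": signal,
            "pulse_rate": np.nan,
        }
    )
    truth = pd.DataFrame(
        {
            "dragon_id": dragon_id,
            "timestamp": micro["timestamp"],
            "state": states,
            "microhabitat": habitats,
        }
    )
    return telemetry, truth


# ---------------------------------------------------------------------------
# respirometry and calibration


def gen_rmr_dataset(
    truth,
    n_individuals: int = 12,
    temps: Sequence[float] = (20.0, 25.0, 30.0, 35.0, 38.0),
    reps: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw respirometry measurements from the log–log metabolic model.

    ``log(vo2) = a + b·log(T) + u_i + ε`` with ``u_i ~ N(0, σ_id²)`` and
    ``ε ~ N(0, noise_sd²)``; ``truth`` is any object with attributes
    ``a, b, sigma_id`` (an :class:`~dragontherm.energetics.RMRModel` fits).
    Sexes alternate male/female across individuals.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    temps = [float(t) for t in temps]
    if any(t < 15.0 or t > 45.0 for t in temps):
        raise ValueError("chamber temperatures must lie in [15, 45] °C")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, truth.sigma_id, size=n_individuals)
    rows = []
    for i in range(n_individuals):
        sex = "M" if i % 2 == 0 else "F"
        for t in temps:
            for _ in range(reps):
                eps = rng.normal(0.0, noise_sd)
                vo2 = np.exp(truth.a + truth.b * np.log(t) + u[i] + eps)
                rows.append((f"ind{i + 1:02d}", sex, t, vo2))
    return pd.DataFrame(rows, columns=["individual_id", "sex", "chamber_temp", "vo2"])


def gen_calibration_dataset(
    slope: float,
    intercept: float,
    n: int,
    noise_sd: float,
    x_range: tuple[float, float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-x points around a calibration line with Gaussian y-noise."""
    if n < 3:
        raise ValueError("need n >= 3")
    lo, hi = x_range
    if hi <= lo:
        raise ValueError("x_range must have positive width")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return x, y


# ---------------------------------------------------------------------------
# climate


@dataclass(frozen=True)
class ClimateScenario:
    """Daily-maximum temperature scenario: seasonal cycle + noise + trend.

    ``base_summer_mean`` is the zero-noise DJF mean before any trend (the
    seasonal term is centred so DJF averages to it exactly).  The trend is
    zero before ``trend_start_year`` and a step (or linear ramp) of
    ``trend_magnitude`` °C from then on.  ``leap_days=False`` drops Feb 29 so
    zero-noise years repeat exactly.
    """

    start_year: int
    end_year: int
    base_summer_mean: float = 27.5
    seasonal_amplitude: float = 8.0
    daily_sd: float = 4.0
    trend_start_year: int | None = None
    trend_magnitude: float = 0.0
    trend_shape: str = "step"
    peak_doy: int = 15  # mid-January
    leap_days: bool = True

    def __post_init__(self) -> None:
        if self.end_year - self.start_year < 1:
            raise ValueError("scenario must span at least 2 years")
        if self.daily_sd < 0:
            raise ValueError("daily_sd must be >= 0")
        if self.trend_shape not in ("step", "ramp"):
            raise ValueError("trend_shape must be 'step' or 'ramp'")


def _ref_doy(date: dt.date) -> int:
    """Day-of-year on a fixed non-leap calendar (Feb 29 shares Feb 28)."""
    if date.month == 2 and date.day == 29:
        date = date.replace(day=28)
    return date.replace(year=2001).timetuple().tm_yday


def _djf_cos_mean(peak_doy: int) -> float:
    days = [dt.date(2001, m, d) for m in (12, 1, 2) for d in range(1, 32) if _valid(m, d)]
    c = [np.cos(2 * np.pi * (_ref_doy(d) - peak_doy) / 365.0) for d in days]
    return float(np.mean(c))


def _valid(month: int, day: int) -> bool:
    try:
        dt.date(2001, month, day)
        return True
    except ValueError:
        return False


def gen_climate(scenario: ClimateScenario, seed: int = 0) -> pd.DataFrame:
    """Daily maximum temperature series for the scenario's year span.

    Returns columns ``date, tmax``.  The same seed always reproduces the
    same series; with ``daily_sd=0`` and no trend every calendar date takes
    the same value in every year.
    """
    rng = np.random.default_rng(seed)
    start = dt.date(scenario.start_year, 1, 1)
    end = dt.date(scenario.end_year, 12, 31)
    dates = pd.date_range(start, end, freq="D").date
    if not scenario.leap_days:
        dates = [d for d in dates if not (d.month == 2 and d.day == 29)]
    cbar = _djf_cos_mean(scenario.peak_doy)
    rows = []
    n_trend_years = (
        scenario.end_year - scenario.trend_start_year + 1
        if scenario.trend_start_year is not None
        else 0
    )
    for d in dates:
        seasonal = scenario.seasonal_amplitude * (
            np.cos(2 * np.pi * (_ref_doy(d) - scenario.peak_doy) / 365.0) - cbar
        )
        trend = 0.0
        if scenario.trend_start_year is not None and d.year >= scenario.trend_start_year:
            if scenario.trend_shape == "step":
                trend = scenario.trend_magnitude
            else:
                trend = (
                    scenario.trend_magnitude
                    * (d.year - scenario.trend_start_year + 1)
                    / max(n_trend_years, 1)
                )
        tmax = scenario.base_summer_mean + seasonal + trend + rng.normal(0.0, scenario.daily_sd)
        rows.append((d, tmax))
    return pd.DataFrame(rows, columns=["date", "tmax"])
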