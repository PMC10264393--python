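"""Analysis-ready transmitter-temperature series.

Turns raw pulse listings into one temperature per dragon per 10-min slot,
restricts to daylight, applies the day-quality filters (≥10 h span, no
≥120 min gap), matches each reading to the microhabitat whose temperature it
most closely resembles, and builds the per-degree / 5 °C-band summaries.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig, SiteGeo
from .solar import DaylightWindow, daylight_window

__all__ = [
    "aggregate_window",
    "build_windows",
    "filter_days",
    "match_microhabitat",
    "match_series",
    "summarize_by_shade",
]

_HABITATS = ("burrow", "shade", "sun")  # fixed tie-break order, buffered first


def aggregate_window(raw, config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Average pulses within each slot's leading listening window.

    ``raw`` is a sequence of (timestamp, pulse) or a frame with those
    columns.  The receiver listens for ``window_seconds`` (90 s) at the head
    of every ``slot_minutes`` slot; pulses within that window are averaged to
    one record per slot, and slots with no pulses are simply absent.  Any
    window with at least one pulse is used — partial dawn windows included.
    """
    if isinstance(raw, pd.DataFrame):
        ts = pd.to_datetime(raw["timestamp"])
        pulse = raw["pulse"].to_numpy(dtype=float)
    else:
        pairs = list(raw)
        ts = pd.to_datetime([p[0] for p in pairs])
        pulse = np.asarray([p[1] for p in pairs], dtype=float)
    if len(ts) == 0:
        return pd.DataFrame({"timestamp": pd.to_datetime([]), "pulse_rate": []})
    if np.any(pulse <= 0):
        raise ValueError("pulse rates must be positive")
    slot = f"{config.slot_minutes}min"
    slot_start = ts.floor(slot)
    offset_s = (ts - slot_start).total_seconds()
    keep = offset_s < config.window_seconds
    df = pd.DataFrame({"timestamp": slot_start[keep], "pulse_rate": pulse[keep]})
    out = df.groupby("timestamp", as_index=False)["pulse_rate"].mean()
    return out.sort_values("timestamp").reset_index(drop=True)


def build_windows(site: SiteGeo, dates: Iterable[dt.date]) -> dict[dt.date, DaylightWindow]:
    """Daylight windows (UTC sunrise/sunset keyed by local date) for a site."""
    return {d: daylight_window(site, d) for d in dates}


def _local_date(ts: pd.Series, utc_offset: float) -> pd.Series:
    return (ts + pd.Timedelta(hours=utc_offset)).dt.date


def filter_days(
    records: pd.DataFrame,
    windows: Mapping[dt.date, DaylightWindow],
    config: PipelineConfig = PipelineConfig(),
    utc_offset: float = 11.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the daylight and day-quality filters.

    Drops records outside [sunrise, sunset]; then drops whole dragon-days
    whose daylight records span < ``min_day_span_hours`` or that contain a
    run of ≥ ``max_gap_slots`` consecutive missing slots on the daylight slot
    grid.  Returns ``(retained_records, day_table)`` where ``day_table`` has
    one row per surviving (dragon_id, date) with its record count.
    """
    if records.empty:
        return records.copy(), pd.DataFrame(columns=["dragon_id", "date", "n_records"])
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec["date"] = _local_date(rec["timestamp"], utc_offset)

    kept_chunks, day_rows = [], []
    slot = pd.Timedelta(minutes=config.slot_minutes)
    for (dragon, day), grp in rec.groupby(["dragon_id", "date"], sort=True):
        win = windows.get(day)
        if win is None:
            continue
        sunrise, sunset = pd.Timestamp(win.sunrise), pd.Timestamp(win.sunset)
        g = grp[(grp["timestamp"] >= sunrise) & (grp["timestamp"] <= sunset)]
        if g.empty:
            continue
        g = g.sort_values("timestamp")
        span_h = (g["timestamp"].iloc[-1] - g["timestamp"].iloc[0]).total_seconds() / 3600
        if span_h < config.min_day_span_hours:
            continue
        # slot grid spanned by the day's records: the gap rule targets
        # interior dropouts; truncated mornings/evenings are the span rule's job
        grid = pd.date_range(g["timestamp"].iloc[0], g["timestamp"].iloc[-1], freq=slot)
        present = grid.isin(set(g["timestamp"]))
        # longest run of consecutive missing grid slots
        longest = run = 0
        for p in present:
            run = 0 if p else run + 1
            longest = max(longest, run)
        if longest >= config.max_gap_slots:
            continue
        kept_chunks.append(g)
        day_rows.append((dragon, day, len(g)))

    retained = (
        pd.concat(kept_chunks, ignore_index=True)
        if kept_chunks
        else rec.iloc[0:0].copy()
    )
    day_table = pd.DataFrame(day_rows, columns=["dragon_id", "date", "n_records"])
    return retained, day_table


def _nearest_habitat(t_trans: float, t_sun: float, t_shade: float, t_burrow: float):
    temps = {"burrow": t_burrow, "shade": t_shade, "sun": t_sun}
    gaps = {h: abs(t_trans - temps[h]) for h in _HABITATS}
    best = min(_HABITATS, key=lambda h: gaps[h])  # ties: burrow -> shade -> sun
    return best, gaps[best]


def match_microhabitat(rec: Mapping, micro: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> dict:
    """Match one telemetry record to its closest microhabitat temperature.

    Requires a microclimate record for the same site within half a slot of
    the record's timestamp; ties in temperature gap resolve in the fixed
    order burrow → shade → sun (buffered habitat preferred).
    """
    ts = pd.Timestamp(rec["timestamp"])
    m = micro[micro["site_id"] == rec["site_id"]]
    if m.empty:
        raise ValueError(f"no microclimate records for site {rec['site_id']}")
    gaps = (pd.to_datetime(m["timestamp"]) - ts).abs()
    i = gaps.idxmin()
    if gaps.loc[i] > pd.Timedelta(minutes=config.slot_minutes / 2):
        raise ValueError(f"no concurrent microclimate record near {ts}")
    row = m.loc[i]
    nearest, gap = _nearest_habitat(
        rec["t_trans"], row["t_sun"], row["t_shade"], row["t_burrow"]
    )
    out = dict(rec)
    out.update(
        t_sun=row["t_sun"], t_shade=row["t_shade"], t_burrow=row["t_burrow"],
        nearest=nearest, abs_gap=gap,
    )
    return out


def match_series(
    records: pd.DataFrame, micro: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Vectorised microhabitat matching for a whole telemetry frame.

    Site-by-site merge on nearest timestamp within half a slot; slots with
    no concurrent microclimate record raise (they should have been dropped
    by the day filters or the microclimate series is incomplete).
    """
    out = []
    tol = pd.Timedelta(minutes=config.slot_minutes / 2)
    for site_id, grp in records.groupby("site_id", sort=False):
        m = micro[micro["site_id"] == site_id]
        if m.empty:
            raise ValueError(f"no microclimate records for site {site_id}")
        g = grp.sort_values("timestamp").copy()
        m = m.sort_values("timestamp")
        merged = pd.merge_asof(
            g,
            m[["timestamp", "t_sun", "t_shade", "t_burrow"]],
            on="timestamp",
            direction="nearest",
            tolerance=tol,
        )
        if merged["t_shade"].isna().any():
            bad = merged.loc[merged["t_shade"].isna(), "timestamp"].iloc[0]
            raise ValueError(f"no concurrent microclimate record near {bad}")
        out.append(merged)
    matched = pd.concat(out, ignore_index=True)
    t = matched["t_trans"].to_numpy()
    cand = np.column_stack(
        [matched["t_burrow"], matched["t_shade"], matched["t_sun"]]
    )
    gaps = np.abs(cand - t[:, None])
    best = np.argmin(gaps, axis=1)  # argmin takes first on ties: burrow, shade, sun
    matched["nearest"] = np.array(["burrow", "shade", "sun"])[best]
    matched["abs_gap"] = gaps[np.arange(len(t)), best]
    return matched


def summarize_by_shade(
    matched: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-degree transmitter means and 5 °C-band temperature histograms.

    Returns ``(per_degree, band_hist)``: mean transmitter temperature for
    each integer degree of shaded ground temperature, and, per 5 °C shade
    band (left-closed, labelled by midpoint), 1 °C-bin frequency counts of
    transmitter, sun, and burrow temperatures.
    """
    if matched.empty:
        raise ValueError("no matched records")
    df = matched.copy()
    df["shade_degree"] = np.floor(df["t_shade"]).astype(int)
    per_degree = (
        df.groupby("shade_degree")["t_trans"]
        .agg(mean_t_trans="mean", n="count")
        .reset_index()
    )

    width = config.band_width_c
    df["band_lo"] = np.floor(df["t_shade"] / width) * width
    rows = []
    for band_lo, grp in df.groupby("band_lo"):
        for var in ("t_trans", "t_sun", "t_burrow"):
            vals = grp[var].to_numpy()
            bins = np.floor(vals).astype(int)
            for b, c in zip(*np.unique(bins, return_counts=True)):
                rows.append((band_lo + width / 2, var, int(b), int(c)))
    band_hist = pd.DataFrame(rows, columns=["band_mid", "variable", "bin", "count"])
    return per_degree, band_hist
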