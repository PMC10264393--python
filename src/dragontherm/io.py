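"""CSV readers and writers for the pipeline's four input streams.

All files are plain comma-separated text with "." decimals and ISO-8601
timestamps (UTC).  The climate reader accepts both a plain two-column
``date,tmax`` dialect and the BOM daily-maximum product layout
(Year/Month/Day columns, header rows skippable).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "FormatError",
    "read_telemetry_csv",
    "write_telemetry_csv",
    "read_microclimate_csv",
    "write_microclimate_csv",
    "read_climate_csv",
    "write_climate_csv",
    "read_rmr_csv",
    "write_rmr_csv",
]

_TELEMETRY_COLS = ["dragon_id", "site_id", "timestamp", "pulse_rate", "signal_strength"]


class FormatError(ValueError):
    """A file does not match the expected CSV contract."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_timestamps(df: pd.DataFrame, path) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        line = int(np.nonzero(ts.isna().to_numpy())[0][0]) + 2  # 1-based + header
        raise FormatError(f"{path}: unparseable timestamp at line {line}")
    df = df.copy()
    df["timestamp"] = ts
    return df


def read_telemetry_csv(
    path, config: PipelineConfig = PipelineConfig()
) -> dict[str, pd.DataFrame]:
    """Read a telemetry CSV into per-dragon time-sorted frames.

    Requires columns ``dragon_id, site_id, timestamp, pulse_rate,
    signal_strength`` (``t_trans`` passed through if present).  Duplicate
    (dragon, timestamp) rows are rejected with an error rather than silently
    dropped — they indicate a corrupted export.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TELEMETRY_COLS, path)
    df = _parse_timestamps(df, path)
    dup = df.duplicated(subset=["dragon_id", "timestamp"])
    if dup.any():
        first = df.loc[dup, ["dragon_id", "timestamp"]].iloc[0]
        raise FormatError(
            f"{path}: duplicate record for dragon {first['dragon_id']} at "
            f"{first['timestamp']}"
        )
    out = {}
    for dragon, grp in df.groupby("dragon_id", sort=True):
        out[str(dragon)] = grp.sort_values("timestamp").reset_index(drop=True)
    return out


def write_telemetry_csv(telemetry: pd.DataFrame, path) -> None:
    df = telemetry.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.9g")


def read_microclimate_csv(path, min_replicates: int = 3) -> pd.DataFrame:
    """Read replicate-logger microclimate rows and average to site-slot means.

    Input is long format: ``site_id, timestamp, habitat, replicate,
    temperature`` with habitat in {sun, shade, burrow}.  Replicates are
    averaged here (the loggers are deployed in ≥3 replicate sets); site-slots
    with fewer than ``min_replicates`` loggers in any habitat are still
    averaged but flagged ``low_replicates``.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "timestamp", "habitat", "replicate", "temperature"], path)
    df = _parse_timestamps(df, path)
    bad = set(df["habitat"].unique()) - {"sun", "shade", "burrow"}
    if bad:
        raise FormatError(f"{path}: unknown habitat label(s) {sorted(bad)}")
    agg = (
        df.groupby(["site_id", "timestamp", "habitat"])["temperature"]
        .agg(["mean", "count"])
        .unstack("habitat")
    )
    means = agg["mean"].rename(columns=lambda h: f"t_{h}")
    counts = agg["count"]
    out = means.reset_index()
    out["low_replicates"] = (counts < min_replicates).any(axis=1).to_numpy()
    for col in ("t_sun", "t_shade", "t_burrow"):
        if col not in out.columns:
            raise FormatError(f"{path}: no rows for habitat {col[2:]!r}")
    return out[["site_id", "timestamp", "t_sun", "t_shade", "t_burrow", "low_replicates"]]


def write_microclimate_csv(replicates: pd.DataFrame, path) -> None:
    df = replicates.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.9g")


def read_climate_csv(path, skip_rows: int = 0) -> pd.DataFrame:
    """Read a daily-maximum temperature record.

    Accepts a plain ``date,tmax`` file or the BOM product layout with
    ``Year, Month, Day`` and a ``Maximum temperature`` column.  Blank Tmax
    entries are kept as missing (NaN).  Duplicate dates are an error;
    physically implausible values (outside −30…60 °C) warn but are kept.
    """
    df = pd.read_csv(path, skiprows=skip_rows)
    cols = {c.strip().lower(): c for c in df.columns}
    if "date" in cols and "tmax" in cols:
        out = pd.DataFrame(
            {
                "date": pd.to_datetime(df[cols["date"]], errors="raise").dt.date,
                "tmax": pd.to_numeric(df[cols["tmax"]], errors="coerce"),
            }
        )
    elif {"year", "month", "day"} <= set(cols):
        tmax_col = next(
            (c for c in df.columns if c.strip().lower().startswith("maximum temperature")),
            None,
        )
        if tmax_col is None:
            raise FormatError(f"{path}: BOM layout lacks a 'Maximum temperature' column")
        out = pd.DataFrame(
            {
                "date": pd.to_datetime(
                    dict(year=df[cols["year"]], month=df[cols["month"]], day=df[cols["day"]])
                ).dt.date,
                "tmax": pd.to_numeric(df[tmax_col], errors="coerce"),
            }
        )
    else:
        raise FormatError(
            f"{path}: expected 'date,tmax' columns or a BOM Year/Month/Day layout"
        )
    if out["date"].duplicated().any():
        d = out.loc[out["date"].duplicated(), "date"].iloc[0]
        raise FormatError(f"{path}: duplicated date {d}")
    wild = out["tmax"].notna() & ((out["tmax"] < -30) | (out["tmax"] > 60))
    if wild.any():
        warnings.warn(
            f"{path}: {int(wild.sum())} Tmax value(s) outside [-30, 60] °C kept as-is"
        )
    return out.reset_index(drop=True)


def write_climate_csv(climate: pd.DataFrame, path) -> None:
    climate.to_csv(path, index=False, float_format="%.9g")


def read_rmr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "sex", "chamber_temp", "vo2"], path)
    if (pd.to_numeric(df["vo2"]) <= 0).any():
        raise FormatError(f"{path}: vo2 values must be positive")
    return df


def write_rmr_csv(rmr: pd.DataFrame, path) -> None:
    rmr.to_csv(path, index=False, float_format="%.9g")
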