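"""Daily aggregation, thermal integrals and 14-day classifier windows.

The degree-day machinery lives here.  The Touzeau index for *L. botrana* is

    Tou(n) = sum_{DOY=1..n} max(0, (TM + Tm)/2 - TB),   TB = 10 degC,

with both daily extremes first clamped to the effective range [0, 30] degC:
sub-zero readings contribute as 0 degC and accumulation saturates at 30 degC.
A generic growing-degree-day (GDD) variant drops the upper cap; a chilling
index counts hours in the cold-exposure band (0, 7.2] degC; a precipitation
index accumulates rainfall.  Every index can start on January 1st,
February 1st, or at the dormancy onset (first autumn day of the previous
year whose maximum stays under 10 degC), and can be computed from daily
extremes or from the semi-hourly samples directly.

The classifier consumes a *feature window*: the per-day features of the 14
days preceding an anchor date, flattened in fixed order, plus the site's
longitude and latitude.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import date_from_doy, doy

logger = logging.getLogger(__name__)

__all__ = [
    "AccumulationSpec",
    "IndexSeries",
    "effective_temperature",
    "aggregate_daily",
    "dormancy_start",
    "accumulate_index",
    "wind_daily_summary",
    "daily_feature_table",
    "project_window",
    "build_windows",
    "WIND_SECTORS",
]

WIND_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
AUTUMN_EQUINOX = (9, 23)
SLOTS_PER_DAY = 48


def effective_temperature(t, lower: float = 0.0, upper: float | None = None):
    """Clamp temperature(s) to the physiologically effective range.

    Sub-`lower` readings count as `lower` (default 0 degC); the upper cap is
    applied only when given (the Touzeau index uses 30 degC, plain GDD none).
    Idempotent.
    """
    return np.clip(t, lower, upper)


def aggregate_daily(records: pd.DataFrame) -> pd.DataFrame:
    """Daily aggregates per station: TM, Tm, precip_total, mean_rh,
    radiation_total, samples.  No clamping here - raw extremes flow through
    and effective-temperature clamping is applied inside the accumulators."""
    if records.empty:
        raise ValueError("aggregate_daily needs at least one record")
    frame = records.copy()
    frame["date"] = pd.to_datetime(frame["timestamp"]).dt.date
    agg = (
        frame.groupby(["station_id", "date"], sort=True)
        .agg(
            TM=("temp", "max"),
            Tm=("temp", "min"),
            precip_total=("precip", "sum"),
            mean_rh=("rh", "mean"),
            radiation_total=("radiation", "sum"),
            samples=("temp", "size"),
        )
        .reset_index()
    )
    return agg


def dormancy_start(
    daily: pd.DataFrame,
    season_year: int,
    threshold: float = 10.0,
    metric: Literal["tmax", "tmean"] = "tmax",
) -> tuple[dt.date, bool]:
    """Dormancy onset: first autumn day of year Y-1 staying under 10 degC.

    Scans from the autumn equinox (Sep 23) of ``season_year - 1`` for the
    earliest day whose daily maximum (or mean, with ``metric='tmean'``) is
    below ``threshold``.  Returns (date, fallback_flag); when no such day
    exists the fallback is Jan 1 of ``season_year`` with the flag set.
    ``daily`` must cover the equinox through Dec 31 of Y-1.
    """
    prev = season_year - 1
    equinox = dt.date(prev, *AUTUMN_EQUINOX)
    frame = daily.copy()
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    autumn = frame[(frame["date"] >= equinox) & (frame["date"] <= dt.date(prev, 12, 31))]
    if autumn.empty or autumn["date"].min() > equinox or autumn["date"].max() < dt.date(prev, 12, 31):
        raise ValueError(f"daily series must cover {equinox}..{prev}-12-31 for dormancy detection")
    value = autumn["TM"] if metric == "tmax" else (autumn["TM"] + autumn["Tm"]) / 2.0
    cold = autumn.loc[value < threshold, "date"]
    if cold.empty:
        return dt.date(season_year, 1, 1), True
    return cold.min(), False


@dataclass(frozen=True)
class AccumulationSpec:
    """What to accumulate, from when, and at what resolution."""

    index_kind: Literal["touzeau", "gdd", "chilling", "precip"] = "touzeau"
    start_rule: Literal["jan1", "feb1", "dormancy"] = "jan1"
    resolution: Literal["daily", "half_hourly"] = "daily"
    base_temp: float = 10.0
    upper_cap: float | None = 30.0
    chill_threshold: float = 7.2

    def __post_init__(self) -> None:
        if self.upper_cap is not None and self.base_temp >= self.upper_cap:
            raise ValueError("base_temp must be below upper_cap")

    def start_date(self, season_year: int, dormancy: dt.date | None = None) -> dt.date:
        if self.start_rule == "jan1":
            return dt.date(season_year, 1, 1)
        if self.start_rule == "feb1":
            return dt.date(season_year, 2, 1)
        if dormancy is None:
            raise ValueError("dormancy start_rule requires a dormancy date")
        return dormancy


@dataclass(frozen=True)
class IndexSeries:
    """Cumulative index per day (degC-day, chill-hours or mm)."""

    spec: AccumulationSpec
    values: pd.Series  # indexed by date, non-decreasing
    start_doy: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if len(v) and np.any(np.diff(v) < -1e-9):
            raise ValueError("cumulative index series must be non-decreasing")

    def first_crossing(self, threshold: float) -> dt.date | None:
        """Earliest date whose cumulative value reaches the threshold (>=)."""
        idx = np.searchsorted(self.values.to_numpy(), threshold)
        if idx >= len(self.values):
            return None
        return self.values.index[int(idx)]


def _daily_increments(daily: pd.DataFrame, spec: AccumulationSpec) -> np.ndarray:
    tm_ = effective_temperature(daily["Tm"].to_numpy(float), 0.0, spec.upper_cap)
    tM_ = effective_temperature(daily["TM"].to_numpy(float), 0.0, spec.upper_cap)
    if spec.index_kind in ("touzeau", "gdd"):
        return np.maximum(0.0, (tM_ + tm_) / 2.0 - spec.base_temp)
    if spec.index_kind == "chilling":
        # Triangle-wave day: temperature spends time uniformly on [Tm, TM],
        # so chill hours = 24 * |(0, thr] intersect [Tm, TM]| / (TM - Tm).
        tm_raw = daily["Tm"].to_numpy(float)
        tM_raw = daily["TM"].to_numpy(float)
        lo = np.maximum(tm_raw, np.nextafter(0.0, 1.0))
        hi = np.minimum(tM_raw, spec.chill_threshold)
        span = tM_raw - tm_raw
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(span > 0, np.clip(hi - lo, 0.0, None) / span, 0.0)
        constant = (span == 0) & (tm_raw > 0) & (tm_raw <= spec.chill_threshold)
        return 24.0 * np.where(constant, 1.0, frac)
    if spec.index_kind == "precip":
        return daily["precip_total"].to_numpy(float)
    raise ValueError(f"unknown index_kind {spec.index_kind}")


def _half_hourly_daily_increments(records: pd.DataFrame, spec: AccumulationSpec) -> pd.Series:
    frame = records.copy()
    frame["date"] = pd.to_datetime(frame["timestamp"]).dt.date
    t = frame["temp"].to_numpy(float)
    if spec.index_kind in ("touzeau", "gdd"):
        eff = effective_temperature(t, 0.0, spec.upper_cap)
        frame["inc"] = np.maximum(0.0, eff - spec.base_temp) / SLOTS_PER_DAY
    elif spec.index_kind == "chilling":
        frame["inc"] = 0.5 * ((t > 0.0) & (t <= spec.chill_threshold))
    elif spec.index_kind == "precip":
        frame["inc"] = frame["precip"].to_numpy(float)
    else:
        raise ValueError(f"unknown index_kind {spec.index_kind}")
    return frame.groupby("date")["inc"].sum()


def accumulate_index(
    daily: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
    spec: AccumulationSpec = AccumulationSpec(),
    season_year: int | None = None,
    dormancy: dt.date | None = None,
    end: dt.date | None = None,
) -> IndexSeries:
    """Cumulative index series from the spec's start date through ``end``.

    ``daily`` feeds the daily resolution, ``records`` the half-hourly one.
    The series starts at the spec's start date (Jan 1 / Feb 1 / dormancy
    onset, possibly in the previous autumn); missing calendar days inside
    the range raise with the offending dates listed.
    """
    source = daily if spec.resolution == "daily" else records
    if source is None:
        raise ValueError(f"{spec.resolution} accumulation needs {'daily' if spec.resolution == 'daily' else 'records'} input")

    if spec.resolution == "daily":
        frame = daily.copy()
        frame["date"] = pd.to_datetime(frame["date"]).dt.date
        inc = pd.Series(_daily_increments(frame, spec), index=frame["date"].to_numpy())
    else:
        inc = _half_hourly_daily_increments(records, spec)
    inc = inc.sort_index()

    if season_year is None:
        season_year = inc.index[-1].year
    start = spec.start_date(season_year, dormancy)
    if end is None:
        end = inc.index[-1]
    if start > end:
        raise ValueError(f"accumulation start {start} is after end {end}")

    wanted = pd.date_range(start, end, freq="D").date
    have = set(inc.index)
    missing = [d for d in wanted if d not in have]
    if missing:
        raise ValueError(f"missing {len(missing)} day(s) inside accumulation range, first: {missing[:5]}")

    window = inc.loc[list(wanted)]
    values = window.cumsum()
    values.index = pd.Index(wanted, name="date")
    return IndexSeries(spec=spec, values=values, start_doy=doy(start))


def wind_daily_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean wind speed per day per 8-point compass sector.

    Sector centres sit at 0, 45, ..., 315 degrees with +/-22.5 deg
    half-width (a 100 deg wind is E).  Unobserved sectors are NaN; the
    window builder imputes them as 0 (calm in that sector).
    """
    frame = records.copy()
    frame["date"] = pd.to_datetime(frame["timestamp"]).dt.date
    sector_idx = (np.floor(np.mod(frame["wind_dir"].to_numpy(float), 360.0) / 45.0 + 0.5) % 8).astype(int)
    frame["sector"] = np.array(WIND_SECTORS)[sector_idx]
    table = frame.pivot_table(index="date", columns="sector", values="wind_speed", aggfunc="mean")
    table = table.reindex(columns=list(WIND_SECTORS))
    table.columns = [f"wind_{s}" for s in WIND_SECTORS]
    return table.reset_index()


DEFAULT_INDEX_SET: tuple[tuple[str, str], ...] = (
    ("touzeau", "jan1"),
    ("touzeau", "feb1"),
    ("touzeau", "dormancy"),
    ("gdd", "jan1"),
    ("gdd", "feb1"),
    ("gdd", "dormancy"),
    ("chilling", "jan1"),
    ("chilling", "dormancy"),
    ("precip", "jan1"),
    ("precip", "dormancy"),
)
MINIMAL_INDEX_SET: tuple[tuple[str, str], ...] = (
    ("touzeau", "jan1"),
    ("gdd", "jan1"),
    ("chilling", "jan1"),
)


def daily_feature_table(
    records: pd.DataFrame,
    season_year: int,
    index_set: Sequence[tuple[str, str]] = DEFAULT_INDEX_SET,
    resolution: Literal["daily", "half_hourly"] = "daily",
    prev_autumn_daily: pd.DataFrame | None = None,
    include_wind: bool = True,
) -> pd.DataFrame:
    """Wide per-day feature table for one station-season.

    Columns: raw daily weather (TM, Tm, precip_total, mean_rh,
    radiation_total), optional 8 wind-sector mean speeds, and one cumulative
    index column per (kind, start_rule) pair named ``idx_{kind}_{rule}``.
    Dormancy-started indexes use the previous autumn when
    ``prev_autumn_daily`` is given, else fall back to Jan 1 (flagged by the
    dormancy detector contract).
    """
    daily = aggregate_daily(records)
    year_daily = daily[pd.to_datetime(daily["date"]).dt.year == season_year].copy()
    table = year_daily[["date", "TM", "Tm", "precip_total", "mean_rh", "radiation_total"]].copy()
    table["date"] = pd.to_datetime(table["date"]).dt.date

    if include_wind:
        wind = wind_daily_summary(records)
        table = table.merge(wind, on="date", how="left")

    dormancy_date: dt.date | None = None
    if any(rule == "dormancy" for _, rule in index_set):
        if prev_autumn_daily is not None:
            dormancy_date, _ = dormancy_start(prev_autumn_daily, season_year)
        else:
            dormancy_date = dt.date(season_year, 1, 1)

    end = table["date"].max()
    all_daily = daily if prev_autumn_daily is None else pd.concat([prev_autumn_daily, daily], ignore_index=True)
    for kind, rule in index_set:
        spec = AccumulationSpec(
            index_kind=kind,
            start_rule=rule,
            resolution=resolution,
            upper_cap=30.0 if kind == "touzeau" else None,
        )
        series = accumulate_index(
            daily=all_daily,
            records=records,
            spec=spec,
            season_year=season_year,
            dormancy=dormancy_date,
            end=end,
        )
        col = series.values.rename(f"idx_{kind}_{rule}").reset_index()
        table = table.merge(col, on="date", how="left")
        table[f"idx_{kind}_{rule}"] = table[f"idx_{kind}_{rule}"].fillna(0.0)  # pre-start days
    return table.sort_values("date").reset_index(drop=True)


def project_window(
    features: pd.DataFrame,
    anchor_date: dt.date,
    longitude: float,
    latitude: float,
    horizon: int = 14,
) -> tuple[np.ndarray, list[str]]:
    """Flatten the ``horizon`` days before ``anchor_date`` into one vector.

    Day ordering is fixed (anchor-14 ... anchor-1); each day contributes the
    feature columns in table order, named ``{col}_d{k}`` where k counts days
    before the anchor (d14 oldest, d1 most recent).  The site's longitude and
    latitude are appended as static features.  Raises when any of the 14 days
    is missing from the table.
    """
    cols = [c for c in features.columns if c != "date"]
    lookup = features.set_index("date")
    days = [anchor_date - dt.timedelta(days=k) for k in range(horizon, 0, -1)]
    missing = [d for d in days if d not in lookup.index]
    if missing:
        raise ValueError(f"insufficient history before {anchor_date}: missing {missing[:3]}")
    block = lookup.loc[days, cols].to_numpy(float)
    vec = np.concatenate([block.ravel(), [longitude, latitude]])
    names = [f"{c}_d{horizon - i}" for i in range(horizon) for c in cols] + ["longitude", "latitude"]
    return vec, names


def build_windows(
    features: pd.DataFrame,
    anchors: Sequence[dt.date],
    longitude: float,
    latitude: float,
    horizon: int = 14,
    max_ffill_days: int = 2,
) -> tuple[np.ndarray, list[str], list[dt.date]]:
    """Vectorized window builder for many anchors of one site-season.

    Wind-sector NaNs become 0 (sector not observed); other missing cells are
    forward-filled up to ``max_ffill_days`` days; anchors whose window still
    contains missing cells (or lacks history) are skipped with a log entry.
    Returns (X, feature_names, kept_anchor_dates).
    """
    table = features.copy().sort_values("date").reset_index(drop=True)
    wind_cols = [c for c in table.columns if c.startswith("wind_")]
    table[wind_cols] = table[wind_cols].fillna(0.0)
    other = [c for c in table.columns if c != "date" and c not in wind_cols]
    table[other] = table[other].ffill(limit=max_ffill_days)

    cols = [c for c in table.columns if c != "date"]
    lookup = table.set_index("date")
    names = [f"{c}_d{horizon - i}" for i in range(horizon) for c in cols] + ["longitude", "latitude"]

    rows, kept, skipped = [], [], 0
    for anchor in anchors:
        days = [anchor - dt.timedelta(days=k) for k in range(horizon, 0, -1)]
        try:
            block = lookup.loc[days, cols].to_numpy(float)
        except KeyError:
            skipped += 1
            continue
        if np.isnan(block).any():
            skipped += 1
            continue
        rows.append(np.concatenate([block.ravel(), [longitude, latitude]]))
        kept.append(anchor)
    if skipped:
        logger.info("build_windows: skipped %d anchor(s) with insufficient history", skipped)
    X = np.vstack(rows) if rows else np.empty((0, len(names)))
    return X, names, kept
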