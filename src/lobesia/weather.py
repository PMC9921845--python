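"""Reading, quality control, gap-filling and spatial assignment of station data.

Station records arrive as semi-hourly CSV (SiAR-like dialect); reanalysis
gap-fill data arrives hourly.  A station-year is usable only when it meets a
coverage rule (fraction of days reporting, fraction of sample-deficient
days); monitoring sites are served by the nearest *valid* station by
great-circle distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import days_in_year

logger = logging.getLogger(__name__)

__all__ = [
    "WEATHER_COLUMNS",
    "StationYearQuality",
    "UnresolvedGapError",
    "read_weather_csv",
    "read_reanalysis_csv",
    "validate_station_year",
    "fill_gaps",
    "haversine_km",
    "assign_nearest_station",
    "assign_sites",
]

WEATHER_COLUMNS = [
    "station_id",
    "timestamp",
    "temp",
    "rh",
    "precip",
    "wind_speed",
    "wind_dir",
    "radiation",
]
SLOTS_PER_DAY = 48
EARTH_RADIUS_KM = 6371.0088


class UnresolvedGapError(ValueError):
    """A gap slot has no covering reanalysis record."""

    def __init__(self, timestamps: list) -> None:
        self.timestamps = timestamps
        preview = ", ".join(str(t) for t in timestamps[:5])
        super().__init__(f"{len(timestamps)} gap slot(s) without reanalysis cover: {preview}")


@dataclass(frozen=True)
class StationYearQuality:
    station_id: str
    year: int
    days_with_data: int
    days_below_sample_threshold: int
    valid: bool


def _clean_records(frame: pd.DataFrame, minutes: tuple[int, ...], what: str) -> pd.DataFrame:
    """Coerce types, drop off-grid/malformed rows with a logged count."""
    frame = frame.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], errors="coerce")
    numeric = [c for c in frame.columns if c not in ("station_id", "timestamp")]
    for c in numeric:
        frame[c] = pd.to_numeric(frame[c], errors="coerce")
    ok = frame["timestamp"].notna() & frame["timestamp"].dt.minute.isin(minutes)
    ok &= frame["temp"].notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: dropped %d malformed/off-grid rows", what, dropped)
    frame = frame.loc[ok].sort_values(["station_id", "timestamp"]).reset_index(drop=True)
    return frame


def read_weather_csv(path) -> pd.DataFrame:
    """Read semi-hourly station records; malformed rows are skipped, not fatal.

    Rows are sorted by (station, timestamp).  Rows whose timestamp minute is
    not :00/:30, or with an unparseable timestamp or temperature, are
    rejected with a logged count.
    """
    frame = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weather CSV missing mandatory columns: {missing}")
    if frame.empty:
        logger.warning("weather CSV %s has an empty data section", path)
        return frame.assign(timestamp=pd.to_datetime(frame["timestamp"]))
    return _clean_records(frame[WEATHER_COLUMNS], (0, 30), f"weather CSV {path}")


def read_reanalysis_csv(path) -> pd.DataFrame:
    """Read hourly reanalysis records (same fields, minute must be :00)."""
    frame = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"reanalysis CSV missing mandatory columns: {missing}")
    if frame.empty:
        return frame.assign(timestamp=pd.to_datetime(frame["timestamp"]))
    return _clean_records(frame[WEATHER_COLUMNS], (0,), f"reanalysis CSV {path}")


def validate_station_year(
    records: pd.DataFrame,
    min_day_frac: float = 0.9,
    min_sample_frac: float = 0.9,
    max_bad_day_frac: float = 0.9,
) -> StationYearQuality:
    """Coverage rule for one station-year.

    valid <=> days_with_data >= ceil(min_day_frac * days_in_year)
          and days_below_sample_threshold < max_bad_day_frac * days_in_year,
    where a day is sample-deficient when it has fewer than
    ceil(min_sample_frac * 48) records.  The second clause's default follows
    the source material as printed ("less than 90%"); pass
    ``max_bad_day_frac=0.1`` for the stricter reading that at most 10% of
    days may be sample-deficient.
    """
    if records.empty:
        raise ValueError("validate_station_year needs at least one record")
    stations = records["station_id"].unique()
    if len(stations) != 1:
        raise ValueError(f"records mix station ids: {stations}")
    ts = pd.to_datetime(records["timestamp"])
    years = ts.dt.year.unique()
    if len(years) != 1:
        raise ValueError(f"records mix years: {years}")
    year = int(years[0])
    n_year = days_in_year(year)

    per_day = ts.dt.date.value_counts()
    days_with_data = int(len(per_day))
    min_samples = math.ceil(min_sample_frac * SLOTS_PER_DAY)
    bad_days = int((per_day < min_samples).sum())

    valid = days_with_data >= math.ceil(min_day_frac * n_year) and bad_days < max_bad_day_frac * n_year
    return StationYearQuality(str(stations[0]), year, days_with_data, bad_days, valid)


def fill_gaps(records: pd.DataFrame, reanalysis: pd.DataFrame) -> pd.DataFrame:
    """Fill missing half-hour slots from hourly reanalysis records.

    The expected grid is every half-hour slot of every calendar day spanned
    by each station's records.  Each missing slot takes all variables from
    the hourly record covering it, except precipitation: the hourly total is
    halved into each of the :00 and :30 slots.  Filled rows carry
    ``imputed=True``; original rows are returned unchanged (``imputed=False``).
    """
    if records.empty:
        return records.assign(imputed=pd.Series(dtype=bool))
    records = records.sort_values(["station_id", "timestamp"])
    out = [records.assign(imputed=False)]

    rean = reanalysis.copy()
    rean["timestamp"] = pd.to_datetime(rean["timestamp"])
    rean_lookup = rean.set_index("timestamp")

    unresolved: list[pd.Timestamp] = []
    for station, grp in records.groupby("station_id", sort=False):
        ts = pd.DatetimeIndex(grp["timestamp"])
        first_day = ts.min().normalize()
        last_day = ts.max().normalize() + pd.Timedelta(hours=23, minutes=30)
        grid = pd.date_range(first_day, last_day, freq="30min")
        missing = grid.difference(ts)
        if missing.empty:
            continue
        hours = missing.floor("h")
        have = hours.isin(rean_lookup.index)
        unresolved.extend(missing[~have])
        if not have.any():
            continue
        src = rean_lookup.loc[hours[have]].reset_index(drop=True)
        filled = src.assign(
            station_id=station,
            timestamp=missing[have],
            precip=src["precip"].to_numpy() / 2.0,
            imputed=True,
        )
        out.append(filled[records.columns.tolist() + ["imputed"]])

    if unresolved:
        raise UnresolvedGapError(sorted(unresolved))
    result = pd.concat(out, ignore_index=True)
    return result.sort_values(["station_id", "timestamp"]).reset_index(drop=True)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a WGS-84 mean-radius sphere, in km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float), np.asarray(lat2, float), np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def assign_nearest_station(
    site_lat: float,
    site_lon: float,
    stations: pd.DataFrame,
    valid_ids: set[str] | None = None,
) -> str:
    """Id of the nearest (valid) station; exact distance ties break to the
    lexicographically smaller station id."""
    pool = stations if valid_ids is None else stations[stations["station_id"].isin(valid_ids)]
    if pool.empty:
        raise ValueError("no valid station available for assignment")
    pool = pool.sort_values("station_id")
    d = haversine_km(site_lat, site_lon, pool["latitude"].to_numpy(), pool["longitude"].to_numpy())
    return str(pool["station_id"].iloc[int(np.argmin(d))])


def assign_sites(
    sites: pd.DataFrame,
    stations: pd.DataFrame,
    validity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign every site its nearest station, optionally per year.

    ``validity``: optional frame (station_id, year, valid).  Returns
    (site_id, year, station_id) when validity is given, else
    (site_id, station_id).
    """
    if validity is None:
        rows = [
            (s.site_id, assign_nearest_station(s.latitude, s.longitude, stations))
            for s in sites.itertuples(index=False)
        ]
        return pd.DataFrame(rows, columns=["site_id", "station_id"])
    rows = []
    for year, grp in validity.groupby("year"):
        ok = set(grp.loc[grp["valid"].astype(bool), "station_id"])
        for s in sites.itertuples(index=False):
            rows.append(
                (s.site_id, int(year), assign_nearest_station(s.latitude, s.longitude, stations, ok))
            )
    return pd.DataFrame(rows, columns=["site_id", "year", "station_id"])
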