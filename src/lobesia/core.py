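"""Shared domain types and small date helpers.

The prediction currency of the whole pipeline is the *flight peak*: the day
of year (DOY, 1-based Julian day) on which adult male captures of a given
Lobesia botrana generation reach their maximum at one monitoring site in one
season.  Every model in the package — the classical Touzeau degree-day
baseline and the neural day-level classifier — ultimately emits flight peaks,
and the evaluator consumes them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FlightPeak",
    "doy",
    "date_from_doy",
    "days_in_year",
    "peaks_to_frame",
    "frame_to_peaks",
]


@dataclass(frozen=True, order=True)
class FlightPeak:
    """One (site, season, generation) flight-peak event.

    ``doy`` is the 1-based Julian day of the year ``season``; generations are
    numbered 1-3 (L. botrana is trivoltine at Mediterranean latitudes).
    """

    site_id: str
    season: int
    generation: int
    doy: int

    def __post_init__(self) -> None:
        if not 1 <= self.generation <= 3:
            raise ValueError(f"generation must be 1-3, got {self.generation}")
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy must be in [1, 366], got {self.doy}")

    @property
    def date(self) -> dt.date:
        return date_from_doy(self.season, self.doy)


def doy(date: dt.date | pd.Timestamp) -> int:
    """1-based day of year."""
    return date.timetuple().tm_yday


def date_from_doy(year: int, day_of_year: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=day_of_year - 1)


def days_in_year(year: int) -> int:
    return 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365


def peaks_to_frame(peaks: Iterable[FlightPeak]) -> pd.DataFrame:
    """Long table (site_id, season, generation, doy), one row per peak."""
    rows = [(p.site_id, p.season, p.generation, p.doy) for p in peaks]
    return pd.DataFrame(rows, columns=["site_id", "season", "generation", "doy"])


def frame_to_peaks(frame: pd.DataFrame) -> list[FlightPeak]:
    return [
        FlightPeak(str(r.site_id), int(r.season), int(r.generation), int(r.doy))
        for r in frame.itertuples(index=False)
    ]


def check_unique_keys(frame: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    """Raise ValueError when (cols) keys repeat — shared guard for evaluators."""
    dup = frame.duplicated(subset=list(cols))
    if dup.any():
        raise ValueError(f"duplicate {what} keys: {frame.loc[dup, list(cols)].values[:5]}")
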