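"""Classical Touzeau degree-day baseline.

Flight peaks are predicted at fixed crossings of the cumulative Touzeau
integral (base 10 degC, extremes clamped to [0, 30] degC, accumulation from
January 1st): 125 degC-day for the first generation, 500 for the second and
950 for the third.  The first day whose cumulative value reaches a
generation's threshold (>=) is that generation's predicted peak DOY.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FlightPeak, doy
from .features import AccumulationSpec, IndexSeries, accumulate_index

__all__ = ["TouzeauParams", "predict_generation_peaks", "predict_from_daily"]


@dataclass(frozen=True)
class TouzeauParams:
    base_temp: float = 10.0
    upper_cap: float | None = 30.0
    thresholds: tuple[float, ...] = (125.0, 500.0, 950.0)
    start_rule: str = "jan1"

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def spec(self) -> AccumulationSpec:
        return AccumulationSpec(
            index_kind="touzeau",
            start_rule=self.start_rule,  # type: ignore[arg-type]
            base_temp=self.base_temp,
            upper_cap=self.upper_cap,
        )

    def perturbed(self, factor: float) -> "TouzeauParams":
        """Same model with all generation thresholds scaled by (1 + factor)."""
        return TouzeauParams(
            self.base_temp,
            self.upper_cap,
            tuple(t * (1.0 + factor) for t in self.thresholds),
            self.start_rule,
        )


def predict_generation_peaks(
    index: IndexSeries,
    params: TouzeauParams = TouzeauParams(),
    site_id: str = "site",
    season: int | None = None,
) -> list[FlightPeak]:
    """Threshold-crossing peaks from a cumulative Touzeau series.

    Generation g's predicted DOY is the first day with index >= thresholds[g];
    generations whose threshold is never reached are absent.  Predicted DOYs
    are non-decreasing across generations by construction.
    """
    values = index.values.to_numpy()
    if len(values) and np.any(np.diff(values) < -1e-9):
        raise ValueError("index series must be cumulative (non-decreasing)")
    peaks: list[FlightPeak] = []
    for g, thr in enumerate(params.thresholds, start=1):
        crossing = index.first_crossing(thr)
        if crossing is None:
            continue
        year = season if season is not None else crossing.year
        peaks.append(FlightPeak(site_id, int(year), g, doy(crossing)))
    return peaks


def predict_from_daily(
    daily: pd.DataFrame,
    params: TouzeauParams = TouzeauParams(),
    site_id: str = "site",
    season: int | None = None,
) -> list[FlightPeak]:
    """Convenience: build the Touzeau index from daily TM/Tm and predict."""
    if season is None:
        season = pd.to_datetime(daily["date"]).dt.year.iloc[-1]
    index = accumulate_index(daily=daily, spec=params.spec(), season_year=int(season))
    return predict_generation_peaks(index, params, site_id, int(season))
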