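"""Feature engineering: clamps, daily aggregation, integrals, windows."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lobesia.features import (
    AccumulationSpec,
    accumulate_index,
    aggregate_daily,
    build_windows,
    daily_feature_table,
    dormancy_start,
    effective_temperature,
    project_window,
    wind_daily_summary,
)


def _daily(tms, tMs, year=2009, precip=None):
    n = len(tms)
    dates = pd.date_range(f"{year}-01-01", periods=n, freq="D").date
    return pd.DataFrame(
        {
            "date": dates,
            "TM": tMs,
            "Tm": tms,
            "precip_total": precip if precip is not None else np.zeros(n),
        }
    )


class TestEffectiveTemperature:
    @pytest.mark.parametrize(
        "t,upper,expected",
        [(-5.0, None, 0.0), (35.0, 30.0, 30.0), (20.0, 30.0, 20.0), (35.0, None, 35.0)],
    )
    def test_clamping(self, t, upper, expected):
        assert effective_temperature(t, upper=upper) == expected

    @given(st.floats(-50, 60))
    def test_idempotent(self, t):
        once = effective_temperature(t, upper=30.0)
        assert effective_temperature(once, upper=30.0) == once


class TestAggregateDaily:
    def test_extremes_and_sums(self):
        stamps = pd.to_datetime(["2009-05-01 00:00", "2009-05-01 08:00", "2009-05-01 16:00"])
        recs = pd.DataFrame(
            {
                "station_id": "Z",
                "timestamp": stamps,
                "temp": [-3.0, 10.0, 22.0],
                "rh": [80.0, 60.0, 40.0],
                "precip": [0.6, 0.6, 0.0],
                "wind_speed": 1.0,
                "wind_dir": 0.0,
                "radiation": 5.0,
            }
        )
        day = aggregate_daily(recs).iloc[0]
        assert day["TM"] == 22.0 and day["Tm"] == -3.0  # clamping deferred
        assert day["precip_total"] == pytest.approx(1.2)
        assert day["mean_rh"] == pytest.approx(60.0)
        assert day["samples"] == 3

    def test_constant_day(self):
        stamps = pd.date_range("2009-05-01", periods=48, freq="30min")
        recs = pd.DataFrame(
            {
                "station_id": "Z",
                "timestamp": stamps,
                "temp": 15.0,
                "rh": 50.0,
                "precip": 0.0,
                "wind_speed": 1.0,
                "wind_dir": 0.0,
                "radiation": 5.0,
            }
        )
        day = aggregate_daily(recs).iloc[0]
        assert day["TM"] == day["Tm"] == 15.0


class TestDormancyStart:
    def _autumn(self, tMs, year=2008):
        start = dt.date(year, 9, 23)
        n = (dt.date(year, 12, 31) - start).days + 1
        values = np.full(n, 15.0)
        values[: len(tMs)] = tMs
        return pd.DataFrame(
            {
                "date": [start + dt.timedelta(days=i) for i in range(n)],
                "TM": values,
                "Tm": values - 5.0,
            }
        )

    def test_scan_finds_first_cold_day(self):
        date, flagged = dormancy_start(self._autumn([12.0, 11.0, 9.0]), 2009)
        assert date == dt.date(2008, 9, 25) and not flagged

    def test_cold_equinox_day_is_boundary(self):
        date, _ = dormancy_start(self._autumn([9.0, 12.0]), 2009)
        assert date == dt.date(2008, 9, 23)

    def test_warm_autumn_falls_back_to_jan1(self):
        frame = self._autumn([])
        date, flagged = dormancy_start(frame, 2009)
        assert date == dt.date(2009, 1, 1) and flagged

    def test_incomplete_autumn_rejected(self):
        frame = self._autumn([12.0]).iloc[:30]
        with pytest.raises(ValueError, match="cover"):
            dormancy_start(frame, 2009)


class TestAccumulateIndex:
    def test_touzeau_brute_force_crossing(self):
        daily = _daily(np.full(20, 10.0), np.full(20, 30.0))
        series = accumulate_index(daily=daily, spec=AccumulationSpec(), season_year=2009)
        # (30 + 10)/2 - 10 = 10 degC-day/day -> 130 on day 13, first >= 125
        assert series.values.iloc[12] == pytest.approx(130.0)
        assert series.first_crossing(125.0) == dt.date(2009, 1, 13)

    def test_all_below_base_accumulates_nothing(self):
        daily = _daily(np.full(30, 2.0), np.full(30, 9.0))
        series = accumulate_index(daily=daily, spec=AccumulationSpec(), season_year=2009)
        assert (series.values == 0).all()

    def test_upper_cap_applies(self):
        hot = _daily(np.full(10, 20.0), np.full(10, 40.0))
        capped = _daily(np.full(10, 20.0), np.full(10, 30.0))
        spec = AccumulationSpec()
        a = accumulate_index(daily=hot, spec=spec, season_year=2009)
        b = accumulate_index(daily=capped, spec=spec, season_year=2009)
        pd.testing.assert_series_equal(a.values, b.values)

    def test_gdd_has_no_cap(self):
        hot = _daily(np.full(5, 20.0), np.full(5, 40.0))
        spec = AccumulationSpec(index_kind="gdd", upper_cap=None)
        series = accumulate_index(daily=hot, spec=spec, season_year=2009)
        assert series.values.iloc[0] == pytest.approx((40 + 20) / 2 - 10)

    def test_half_hourly_equals_daily_on_constant_days(self):
        stamps = pd.date_range("2009-01-01", periods=10 * 48, freq="30min")
        recs = pd.DataFrame(
            {"station_id": "Z", "timestamp": stamps, "temp": 18.0, "precip": 0.0}
        )
        daily = _daily(np.full(10, 18.0), np.full(10, 18.0))
        a = accumulate_index(
            records=recs, spec=AccumulationSpec(resolution="half_hourly"), season_year=2009
        )
        b = accumulate_index(daily=daily, spec=AccumulationSpec(), season_year=2009)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_chilling_constant_cold_day_counts_full_day(self):
        daily = _daily(np.full(2, 5.0), np.full(2, 5.0))
        spec = AccumulationSpec(index_kind="chilling", upper_cap=None)
        series = accumulate_index(daily=daily, spec=spec, season_year=2009)
        assert series.values.iloc[-1] == pytest.approx(48.0)  # 24 h x 2 days

    def test_chilling_half_hourly_counts_half_hours(self):
        stamps = pd.date_range("2009-01-01", periods=48, freq="30min")
        temp = np.full(48, 20.0)
        temp[:10] = 5.0  # 10 samples in (0, 7.2] -> 5 h
        recs = pd.DataFrame({"station_id": "Z", "timestamp": stamps, "temp": temp, "precip": 0.0})
        spec = AccumulationSpec(index_kind="chilling", resolution="half_hourly", upper_cap=None)
        series = accumulate_index(records=recs, spec=spec, season_year=2009)
        assert series.values.iloc[0] == pytest.approx(5.0)

    def test_feb1_start_zeroes_january(self):
        daily = _daily(np.full(60, 15.0), np.full(60, 25.0))
        spec = AccumulationSpec(start_rule="feb1")
        series = accumulate_index(daily=daily, spec=spec, season_year=2009)
        assert series.start_doy == 32
        assert series.values.index[0] == dt.date(2009, 2, 1)
        assert series.values.iloc[0] == pytest.approx(10.0)

    def test_missing_days_inside_range_rejected(self):
        daily = _daily(np.full(20, 15.0), np.full(20, 25.0)).drop(index=10)
        with pytest.raises(ValueError, match="missing 1 day"):
            accumulate_index(daily=daily, spec=AccumulationSpec(), season_year=2009)

    @given(st.integers(0, 2**31 - 1))
    def test_cumulative_series_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        tm = rng.uniform(-5, 20, 30)
        tM = tm + rng.uniform(0, 15, 30)
        kind = rng.choice(["touzeau", "gdd", "chilling"])
        spec = AccumulationSpec(index_kind=kind, upper_cap=30.0 if kind == "touzeau" else None)
        series = accumulate_index(daily=_daily(tm, tM), spec=spec, season_year=2009)
        assert (np.diff(series.values.to_numpy()) >= -1e-12).all()

    def test_warmer_series_accumulates_no_less(self):
        rng = np.random.default_rng(5)
        tm = rng.uniform(0, 15, 40)
        tM = tm + rng.uniform(0, 10, 40)
        cool = _daily(tm, tM)
        warm = _daily(tm + 2.0, tM + 2.0)
        spec = AccumulationSpec()
        a = accumulate_index(daily=cool, spec=spec, season_year=2009).values
        b = accumulate_index(daily=warm, spec=spec, season_year=2009).values
        assert (b.to_numpy() >= a.to_numpy() - 1e-12).all()


class TestWindSummary:
    def _recs(self, dirs, speeds, when="2009-03-01"):
        stamps = pd.date_range(when, periods=len(dirs), freq="30min")
        return pd.DataFrame(
            {"station_id": "Z", "timestamp": stamps, "wind_dir": dirs, "wind_speed": speeds}
        )

    def test_single_sector_mean(self):
        out = wind_daily_summary(self._recs([0.0, 359.0, 1.0], [3.0, 3.0, 3.0]))
        assert out["wind_N"].iloc[0] == pytest.approx(3.0)
        assert out.drop(columns=["date", "wind_N"]).isna().all().all()

    def test_boundary_direction_classification(self):
        out = wind_daily_summary(self._recs([100.0], [2.0]))
        assert out["wind_E"].iloc[0] == 2.0  # 100 deg lies in (67.5, 112.5]

    def test_sector_mean_of_two(self):
        out = wind_daily_summary(self._recs([350.0, 10.0], [2.0, 4.0]))
        assert out["wind_N"].iloc[0] == pytest.approx(3.0)


class TestWindows:
    def _features(self, n=30, f=3, year=2009):
        dates = pd.date_range(f"{year}-03-01", periods=n, freq="D").date
        data = {"date": dates}
        for i in range(f):
            data[f"f{i}"] = np.arange(n, dtype=float) + i
        return pd.DataFrame(data)

    def test_window_width_is_14_x_features_plus_statics(self):
        table = self._features(f=10)
        vec, names = project_window(table, dt.date(2009, 3, 20), -1.0, 41.5)
        assert len(vec) == len(names) == 14 * 10 + 2

    def test_projection_deterministic_and_ordered(self):
        table = self._features()
        a, names = project_window(table, dt.date(2009, 3, 20), -1.0, 41.5)
        b, _ = project_window(table, dt.date(2009, 3, 20), -1.0, 41.5)
        assert np.array_equal(a, b)
        assert names[0] == "f0_d14" and names[-3] == "f2_d1"
        # oldest day first: anchor Mar 20 -> d14 is Mar 6 (value 5.0 for f0)
        assert a[0] == 5.0

    def test_insufficient_history_raises(self):
        table = self._features(n=5)
        with pytest.raises(ValueError, match="insufficient history"):
            project_window(table, dt.date(2009, 3, 4), -1.0, 41.5)

    def test_build_windows_skips_short_history_and_imputes_wind(self):
        table = self._features(n=30)
        table["wind_N"] = np.nan
        anchors = [dt.date(2009, 3, 10), dt.date(2009, 3, 20)]
        X, names, kept = build_windows(table, anchors, -1.0, 41.5)
        assert kept == [dt.date(2009, 3, 20)]
        wind_cols = [i for i, n in enumerate(names) if n.startswith("wind_N")]
        assert np.allclose(X[0, wind_cols], 0.0)


def test_daily_feature_table_has_indexes_and_wind(calm_records):
    table = daily_feature_table(calm_records, 2009)
    assert len(table) == 365
    for col in ("idx_touzeau_jan1", "idx_gdd_jan1", "idx_chilling_jan1", "wind_NW", "TM"):
        assert col in table.columns
    tou = table["idx_touzeau_jan1"].to_numpy()
    assert (np.diff(tou) >= 0).all()
    # the uncapped GDD integral dominates the capped Touzeau integral
    assert (table["idx_gdd_jan1"] >= table["idx_touzeau_jan1"] - 1e-9).all()
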