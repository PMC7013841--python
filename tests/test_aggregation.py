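"""Daily aggregation: completeness rules, 8-h windows, exposure tables."""

import numpy as np
import pandas as pd
import pytest

from aqra.aggregation import (
    build_daily_exposure,
    daily_8h_metric,
    daily_mean_24h,
    validate_hourly,
)


def series_for(day="2015-06-01", values=None):
    """Hourly series for one day; values is {hour: concentration}."""
    start = pd.Timestamp(day)
    index = [start + pd.Timedelta(hours=h) for h in values]
    return pd.Series(list(values.values()), index=index)


class TestDailyMean:
    @pytest.mark.parametrize("n_present", range(25))
    def test_completeness_rule_exhaustive(self, n_present):
        """The 75% rule admits exactly 18..24 present hours of 24."""
        values = {h: 5.0 for h in range(n_present)}
        result = daily_mean_24h(series_for(values=values), "2015-06-01")
        assert result.completeness == pytest.approx(n_present / 24)
        if n_present >= 18:
            assert result.value == pytest.approx(5.0)
        else:
            assert result.value is None

    def test_mean_of_present_hours_only(self):
        values = {h: float(h) for h in range(18)}
        result = daily_mean_24h(series_for(values=values), "2015-06-01")
        assert result.value == pytest.approx(np.mean(range(18)))

    def test_constant_day(self):
        values = {h: 3.25 for h in range(24)}
        assert daily_mean_24h(series_for(values=values), "2015-06-01").value == 3.25


class TestEightHourMetric:
    def test_constant_series_returns_constant(self):
        values = {h: 2.5 for h in range(24)}
        assert daily_8h_metric(series_for(values=values), "2015-06-01").value == 2.5

    def test_peak_block_drives_maximum(self):
        values = {h: 0.0 for h in range(24)}
        values.update({h: 10.0 for h in range(8, 16)})
        result = daily_8h_metric(series_for(values=values), "2015-06-01")
        assert result.value == pytest.approx(10.0)

    def test_mean_reduce_averages_windows(self):
        values = {h: 0.0 for h in range(24)}
        values.update({h: 10.0 for h in range(8, 16)})
        result = daily_8h_metric(
            series_for(values=values), "2015-06-01", reduce="mean", cross_midnight=False
        )
        assert 0.0 < result.value < 10.0

    def test_all_hours_absent_is_missing(self):
        result = daily_8h_metric(series_for(values={}), "2015-06-01")
        assert result.value is None
        assert result.completeness == 0.0

    def test_window_validity_six_of_eight(self):
        # Exactly 6 present hours inside one window -> valid; 5 -> not.
        values6 = {h: 4.0 for h in range(6)}
        assert daily_8h_metric(series_for(values=values6), "2015-06-01").value == 4.0
        values5 = {h: 4.0 for h in range(5)}
        assert daily_8h_metric(series_for(values=values5), "2015-06-01").value is None

    def test_cross_midnight_window_sees_next_day(self):
        values = {h: 1.0 for h in (22, 23)}
        series = series_for(values=values)
        next_day = pd.Series(
            [1.0] * 6,
            index=pd.date_range("2015-06-02 00:00:00", periods=6, freq="h"),
        )
        series = pd.concat([series, next_day])
        crossing = daily_8h_metric(series, "2015-06-01", cross_midnight=True)
        truncated = daily_8h_metric(series, "2015-06-01", cross_midnight=False)
        assert crossing.value == pytest.approx(1.0)
        assert truncated.value is None


class TestBuildDailyExposure:
    def test_single_complete_day_pm10_boundary(self, kuwait_table, make_hourly):
        hourly = make_hourly({h: 90.0 for h in range(24)})
        exposure = build_daily_exposure(hourly, kuwait_table)
        assert len(exposure) == 1
        assert exposure.loc[0, "aqi_PM10"] == pytest.approx(50.0)
        assert exposure.loc[0, "completeness_PM10"] == 1.0

    def test_empty_input_gives_empty_output(self, kuwait_table):
        empty = pd.DataFrame(
            columns=["station_id", "governorate", "timestamp", "pollutant", "concentration"]
        )
        assert build_daily_exposure(empty, kuwait_table).empty

    def test_row_count_is_dates_times_governorates(self, kuwait_table, make_hourly):
        frames = []
        for gov, station in [("Ahmadi", "S1"), ("Jahra", "S2")]:
            for day in ["2015-06-01", "2015-06-02", "2015-06-03"]:
                frames.append(
                    make_hourly(
                        {h: 50.0 for h in range(24)},
                        governorate=gov,
                        station=station,
                        date=day,
                    )
                )
        exposure = build_daily_exposure(pd.concat(frames), kuwait_table)
        assert len(exposure) == 6
        assert exposure["completeness_PM10"].between(0, 1).all()

    def test_aqi_of_aggregate_not_aggregate_of_aqi(self, kuwait_table, make_hourly):
        """Averaging happens on concentrations before the AQI conversion.

        Half the hours sit below the Good/Moderate knee and half above it;
        because the conversion is piecewise linear, converting first and
        averaging after would give a different (wrong) answer.
        """
        values = {h: (40.0 if h < 12 else 340.0) for h in range(24)}
        hourly = make_hourly(values)
        exposure = build_daily_exposure(hourly, kuwait_table)
        from aqra.breakpoints import compute_aqi

        daily_conc = np.mean(list(values.values()))
        expected = compute_aqi("PM10", daily_conc, kuwait_table).index
        mean_of_aqis = np.mean(
            [compute_aqi("PM10", v, kuwait_table).index for v in values.values()]
        )
        assert exposure.loc[0, "aqi_PM10"] == pytest.approx(expected)
        assert abs(expected - mean_of_aqis) > 1.0

    def test_matches_scalar_reference_ops(self, kuwait_table):
        """The vectorized bulk path agrees with the per-day operations."""
        rng = np.random.default_rng(42)
        start = pd.Timestamp("2015-03-01")
        rows = []
        for pollutant, level in [("PM10", 120.0), ("O3", 0.04)]:
            for h in range(5 * 24):
                if rng.random() < 0.25:
                    continue  # random gaps
                rows.append(
                    {
                        "station_id": "S1",
                        "governorate": "Ahmadi",
                        "timestamp": start + pd.Timedelta(hours=h),
                        "pollutant": pollutant,
                        "concentration": level * (1 + 0.3 * rng.random()),
                    }
                )
        hourly = pd.DataFrame(rows)
        exposure = build_daily_exposure(hourly, kuwait_table)
        from aqra.breakpoints import compute_aqi

        for _, row in exposure.iterrows():
            date = pd.Timestamp(row["date"])
            for pollutant, op in [("PM10", daily_mean_24h), ("O3", daily_8h_metric)]:
                series = hourly[hourly["pollutant"] == pollutant].set_index(
                    "timestamp"
                )["concentration"]
                ref = op(series, date)
                assert row[f"completeness_{pollutant}"] == pytest.approx(
                    ref.completeness
                )
                if ref.value is None:
                    assert np.isnan(row[f"aqi_{pollutant}"])
                else:
                    assert row[f"aqi_{pollutant}"] == pytest.approx(
                        compute_aqi(pollutant, ref.value, kuwait_table).index
                    )

    def test_duplicate_hourly_reading_rejected(self, make_hourly):
        hourly = pd.concat([make_hourly({0: 1.0}), make_hourly({0: 2.0})])
        with pytest.raises(ValueError, match="duplicate"):
            validate_hourly(hourly)

    def test_station_in_two_governorates_rejected(self, make_hourly):
        a = make_hourly({0: 1.0}, governorate="Ahmadi")
        b = make_hourly({1: 1.0}, governorate="Jahra")
        with pytest.raises(ValueError, match="multiple governorates"):
            validate_hourly(pd.concat([a, b]))
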