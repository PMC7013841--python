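"""Hourly-to-daily aggregation of monitor readings.

PM10, NO2 and SO2 use the 24-hour mean of the calendar day; O3 and CO use
an 8-hour time average (by default the daily maximum over the 24 rolling
8-hour windows starting on the day, the common regulatory convention).
Every average is subject to a 75% completeness rule: a 24-hour mean needs
at least 18 present hours, an 8-hour window at least 6.  Averaging always
happens on concentrations; the AQI conversion is applied to the daily
aggregate, never averaged itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breakpoints import (
    WINDOW_8H,
    WINDOW_24H,
    BreakpointTable,
    compute_aqi,
)

COMPLETENESS_THRESHOLD = 0.75

HOURLY_COLUMNS = ["station_id", "governorate", "timestamp", "pollutant", "concentration"]


@dataclass(frozen=True)
class DailyValue:
    """A daily concentration metric plus the completeness that backed it."""

    value: float | None
    completeness: float


def _day_slice(series: pd.Series, date: pd.Timestamp, hours: int) -> pd.Series:
    """Hourly values (NaN-padded) for ``hours`` hours starting at midnight."""
    start = pd.Timestamp(date).normalize()
    index = pd.date_range(start, periods=hours, freq="h")
    return series.reindex(index)


def daily_mean_24h(hourly_series: pd.Series, date) -> DailyValue:
    """24-hour mean for one station/pollutant on one calendar day.

    ``hourly_series`` is indexed by timestamp.  Returns the mean of present
    hours when at least 18 of 24 are present, otherwise a missing value;
    the completeness fraction is reported either way.
    """
    values = _day_slice(hourly_series, date, 24)
    present = values.notna().sum()
    completeness = present / 24.0
    if completeness >= COMPLETENESS_THRESHOLD:
        return DailyValue(float(values.mean()), completeness)
    return DailyValue(None, completeness)


def daily_8h_metric(
    hourly_series: pd.Series,
    date,
    *,
    reduce: str = "max",
    cross_midnight: bool = True,
) -> DailyValue:
    """Daily 8-hour time-average metric for O3 or CO.

    Rolling 8-hour means are anchored at each of the 24 start hours of the
    day; a window is valid when at least 6 of its 8 hours are present.  The
    daily metric is the maximum valid window mean (``reduce="mean"``
    averages the valid windows instead).  Windows extend into the next day
    unless ``cross_midnight`` is False, which truncates the anchor set so
    no window leaves the date.  Completeness is the best window
    completeness, so a present metric always implies completeness >= 0.75.
    """
    span = 24 + 7 if cross_midnight else 24
    values = _day_slice(hourly_series, date, span).to_numpy(dtype=float)
    n_windows = 24 if cross_midnight else 24 - 7
    window_means, best_completeness = [], 0.0
    for start in range(n_windows):
        window = values[start : start + 8]
        present = int(np.sum(~np.isnan(window)))
        completeness = present / 8.0
        best_completeness = max(best_completeness, completeness)
        if completeness >= COMPLETENESS_THRESHOLD:
            window_means.append(float(np.nanmean(window)))
    if not window_means:
        return DailyValue(None, best_completeness)
    if reduce == "max":
        return DailyValue(max(window_means), best_completeness)
    if reduce == "mean":
        return DailyValue(float(np.mean(window_means)), best_completeness)
    raise ValueError(f"unknown reduce {reduce!r}; use 'max' or 'mean'")


def validate_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Check schema and uniqueness of (station, pollutant, hour)."""
    missing = set(HOURLY_COLUMNS) - set(hourly.columns)
    if missing:
        raise ValueError(f"hourly table lacks columns {sorted(missing)}")
    out = hourly.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    dup = out.duplicated(subset=["station_id", "pollutant", "timestamp"])
    if dup.any():
        first = out.loc[dup.idxmax()]
        raise ValueError(
            "duplicate hourly reading for "
            f"({first.station_id}, {first.pollutant}, {first.timestamp})"
        )
    station_gov = out[["station_id", "governorate"]].drop_duplicates()
    per_station = station_gov.groupby("station_id")["governorate"].nunique()
    if (per_station > 1).any():
        bad = per_station[per_station > 1].index.tolist()
        raise ValueError(f"stations mapped to multiple governorates: {bad}")
    return out


def build_daily_exposure(
    hourly: pd.DataFrame,
    breakpoint_table: BreakpointTable,
    *,
    eight_hour_reduce: str = "max",
    cross_midnight: bool = True,
) -> pd.DataFrame:
    """Aggregate an hourly reading table to one row per (date, governorate).

    Output columns: ``date``, ``governorate``, then ``aqi_<pollutant>``
    and ``completeness_<pollutant>`` for every pollutant present in the
    input.  Daily concentrations are converted through ``compute_aqi``;
    days failing the completeness rule get a missing AQI.
    """
    hourly = validate_hourly(hourly)
    if hourly.empty:
        return pd.DataFrame(columns=["date", "governorate"])
    start = hourly["timestamp"].min().normalize()
    end = hourly["timestamp"].max().normalize()
    dates = pd.date_range(start, end, freq="D")
    n_days = len(dates)
    # Full hourly grid with 7 spare hours so 8-h windows may cross midnight.
    grid = pd.date_range(start, periods=n_days * 24 + 7, freq="h")
    pollutants = sorted(hourly["pollutant"].unique())
    records: list[pd.DataFrame] = []
    for governorate, gov_frame in hourly.groupby("governorate", sort=True):
        block = pd.DataFrame({"date": dates.date, "governorate": governorate})
        for pollutant in pollutants:
            sub = gov_frame[gov_frame["pollutant"] == pollutant]
            values = (
                sub.set_index("timestamp")["concentration"]
                .reindex(grid)
                .to_numpy(dtype=float)
            )
            if pollutant in WINDOW_24H:
                daily, completeness = _all_days_24h(values, n_days)
            elif pollutant in WINDOW_8H:
                daily, completeness = _all_days_8h(
                    values,
                    n_days,
                    reduce=eight_hour_reduce,
                    cross_midnight=cross_midnight,
                )
            else:
                raise ValueError(f"no averaging window for {pollutant!r}")
            aqi = np.full(n_days, np.nan)
            for i, value in enumerate(daily):
                if not np.isnan(value):
                    aqi[i] = compute_aqi(pollutant, value, breakpoint_table).index
            block[f"aqi_{pollutant}"] = aqi
            block[f"completeness_{pollutant}"] = completeness
        records.append(block)
    return pd.concat(records, ignore_index=True)


def _all_days_24h(values: np.ndarray, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 24-h means with the 18-of-24 rule for every day at once."""
    day_matrix = values[: n_days * 24].reshape(n_days, 24)
    finite = ~np.isnan(day_matrix)
    present = finite.sum(axis=1)
    completeness = present / 24.0
    sums = np.where(finite, day_matrix, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(present > 0, sums / present, np.nan)
    means[completeness < COMPLETENESS_THRESHOLD] = np.nan
    return means, completeness


def _all_days_8h(
    values: np.ndarray,
    n_days: int,
    *,
    reduce: str = "max",
    cross_midnight: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized daily 8-h window metric mirroring :func:`daily_8h_metric`."""
    if reduce not in ("max", "mean"):
        raise ValueError(f"unknown reduce {reduce!r}; use 'max' or 'mean'")
    finite = ~np.isnan(values)
    kernel = np.ones(8)
    counts = np.convolve(finite.astype(float), kernel, mode="full")[7 : len(values)]
    sums = np.convolve(np.where(finite, values, 0.0), kernel, mode="full")[
        7 : len(values)
    ]
    # counts[i]/sums[i] describe the window starting at hour i.
    with np.errstate(invalid="ignore", divide="ignore"):
        window_means = np.where(counts > 0, sums / counts, np.nan)
    window_completeness = counts / 8.0
    valid = window_completeness >= COMPLETENESS_THRESHOLD
    n_windows = 24 if cross_midnight else 24 - 7
    daily = np.full(n_days, np.nan)
    completeness = np.zeros(n_days)
    for day in range(n_days):
        sl = slice(day * 24, day * 24 + n_windows)
        w_valid = valid[sl]
        completeness[day] = float(np.max(window_completeness[sl], initial=0.0))
        if w_valid.any():
            means = window_means[sl][w_valid]
            daily[day] = float(np.max(means) if reduce == "max" else np.mean(means))
    return daily, completeness
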