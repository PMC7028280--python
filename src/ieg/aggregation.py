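"""Representative annual averages under regulatory completeness criteria.

A day of hourly gas measurements is valid when at least 18 of its 24 hours
are valid.  An annual average is included when the site has a minimum number
of valid operating days for its sampling schedule (244 for daily/hourly, 61
for 1-in-3, 41 for 1-in-6) and no stretch of more than 45 consecutive
calendar days without a valid measurement.  Ozone uses the daily maximum of
the 8-hour moving average (18 or more operating hours per day) averaged over
the May-September season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_VALID_HOURS = 18
MAX_GAP_DAYS = 45
#: Minimum valid days per year by sampling schedule.
MIN_DAYS = {"1-in-1": 244, "1-in-3": 61, "1-in-6": 41}

SEASON_START = (5, 1)  # May 1
SEASON_END = (9, 30)  # Sep 30
SEASON_DAYS = 153
#: ceil(2/3 of season days): minimum valid days for a season average.
SEASON_MIN_DAYS = -(-2 * SEASON_DAYS // 3)  # 102
#: The 45-day annual gap rule scaled to the season length, rounded.
SEASON_MAX_GAP = round(MAX_GAP_DAYS * SEASON_DAYS / 365)  # 19


@dataclass(frozen=True)
class DailyValue:
    date: pd.Timestamp
    value: float
    n_valid_hours: int
    valid: bool


@dataclass(frozen=True)
class AnnualRecord:
    site_id: str
    year: int
    pollutant: str
    value: float
    sqrt_value: float
    n_days_used: int
    included: bool
    exclusion_reason: str  # "none" | "too_few_days" | "long_gap"


def daily_average(hourly: np.ndarray, date=None) -> DailyValue:
    """24-hour mean; valid only with >= 18 valid (non-NaN) hourly values."""
    hourly = np.asarray(hourly, dtype=float)
    if hourly.size > 24:
        raise ValueError("more than 24 hourly slots")
    n_valid = int(np.sum(~np.isnan(hourly)))
    valid = n_valid >= MIN_VALID_HOURS
    value = float(np.nanmean(hourly)) if n_valid else float("nan")
    return DailyValue(date=date, value=value, n_valid_hours=n_valid, valid=valid)


def daily_max8h(hourly: np.ndarray, date=None) -> DailyValue:
    """Daily maximum 8-hour moving average for ozone.

    Windows start at hours 0..16 (never crossing midnight); a window
    contributes only if at least 6 of its 8 hours are valid, in which case its
    value is the mean of its valid hours.  The day is valid with >= 18
    operating hours and at least one contributing window.
    """
    hourly = np.asarray(hourly, dtype=float)
    if hourly.size > 24:
        raise ValueError("more than 24 hourly slots")
    padded = np.full(24, np.nan)
    padded[: hourly.size] = hourly
    n_valid = int(np.sum(~np.isnan(padded)))
    best = float("nan")
    for start in range(17):
        win = padded[start : start + 8]
        n = int(np.sum(~np.isnan(win)))
        if n >= 6:
            m = float(np.nanmean(win))
            if np.isnan(best) or m > best:
                best = m
    valid = n_valid >= MIN_VALID_HOURS and not np.isnan(best)
    return DailyValue(date=date, value=best, n_valid_hours=n_valid, valid=valid)


def _longest_gap(valid_dates: pd.DatetimeIndex, start, end) -> int:
    """Longest run of calendar days in [start, end] without a valid value.

    Counts interior gaps between consecutive valid dates and the leading and
    trailing stretches of the period.
    """
    if len(valid_dates) == 0:
        return (end - start).days + 1
    d = valid_dates.sort_values()
    gaps = [(d[0] - start).days, (end - d[-1]).days]
    if len(d) > 1:
        gaps.extend((np.diff(d.values).astype("timedelta64[D]").astype(int) - 1))
    return int(max(gaps))


def _to_frame(daily) -> pd.DataFrame:
    if isinstance(daily, pd.DataFrame):
        df = daily.copy()
        df["date"] = pd.to_datetime(df["date"])
        return df
    return pd.DataFrame(
        {"date": [pd.to_datetime(d.date) for d in daily],
         "value": [d.value for d in daily],
         "valid": [d.valid for d in daily]}
    )


def annual_average(
    daily,
    schedule: str = "1-in-1",
    site_id: str = "",
    pollutant: str = "",
) -> AnnualRecord:
    """Annual mean of valid daily values under the completeness criteria.

    ``daily`` is a sequence of :class:`DailyValue` or a DataFrame with columns
    ``date, value, valid``, all within one calendar year.  Inclusion requires
    at least the schedule's minimum number of valid days and no gap longer
    than 45 consecutive calendar days without a valid measurement (leading and
    trailing stretches of the year count as gaps).
    """
    if schedule not in MIN_DAYS:
        raise ValueError(f"unknown schedule {schedule!r}")
    df = _to_frame(daily)
    years = df["date"].dt.year.unique()
    if len(years) > 1:
        raise ValueError("daily values span multiple years")
    year = int(years[0]) if len(years) else 0
    ok = df[df["valid"]]
    n_used = len(ok)
    reason = "none"
    if n_used < MIN_DAYS[schedule]:
        reason = "too_few_days"
    else:
        gap = _longest_gap(
            pd.DatetimeIndex(ok["date"]),
            pd.Timestamp(year=year, month=1, day=1),
            pd.Timestamp(year=year, month=12, day=31),
        )
        if gap > MAX_GAP_DAYS:
            reason = "long_gap"
    included = reason == "none"
    value = float(ok["value"].mean()) if included else float("nan")
    return AnnualRecord(
        site_id=site_id,
        year=year,
        pollutant=pollutant,
        value=value,
        sqrt_value=float(np.sqrt(value)) if included else float("nan"),
        n_days_used=n_used,
        included=included,
        exclusion_reason=reason,
    )


def ozone_season_average(
    daily, site_id: str = "", pollutant: str = "ozone"
) -> AnnualRecord:
    """May-September mean of valid daily 8-hour-max values.

    Inclusion requires at least two thirds of the 153 season days valid and no
    run of more than 19 consecutive season days without a valid value (the
    45-day annual rule scaled to the season length).
    """
    df = _to_frame(daily)
    years = df["date"].dt.year.unique()
    if len(years) > 1:
        raise ValueError("daily values span multiple years")
    year = int(years[0]) if len(years) else 0
    start = pd.Timestamp(year=year, month=SEASON_START[0], day=SEASON_START[1])
    end = pd.Timestamp(year=year, month=SEASON_END[0], day=SEASON_END[1])
    season = df[(df["date"] >= start) & (df["date"] <= end)]
    ok = season[season["valid"]]
    n_used = len(ok)
    reason = "none"
    if n_used < SEASON_MIN_DAYS:
        reason = "too_few_days"
    elif _longest_gap(pd.DatetimeIndex(ok["date"]), start, end) > SEASON_MAX_GAP:
        reason = "long_gap"
    included = reason == "none"
    value = float(ok["value"].mean()) if included else float("nan")
    return AnnualRecord(
        site_id=site_id,
        year=year,
        pollutant=pollutant,
        value=value,
        sqrt_value=float(np.sqrt(value)) if included else float("nan"),
        n_days_used=n_used,
        included=included,
        exclusion_reason=reason,
    )


def aggregate_hourly(
    hourly: pd.DataFrame,
    metric: str = "mean",
    schedule: str = "1-in-1",
    site_id: str = "",
    pollutant: str = "",
) -> AnnualRecord:
    """Hourly series (``timestamp, value``) -> annual record in one step.

    ``metric`` is ``"mean"`` (24-hour averages, annual criteria) or
    ``"max8h-season"`` (ozone daily 8-hour maxima, May-September criteria).
    """
    if metric not in {"mean", "max8h-season"}:
        raise ValueError(f"unknown metric {metric!r}")
    df = hourly.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    reducer = daily_average if metric == "mean" else daily_max8h
    rows = []
    for day, grp in df.groupby(df["timestamp"].dt.normalize()):
        slot = np.full(24, np.nan)
        slot[grp["timestamp"].dt.hour.to_numpy()] = grp["value"].to_numpy()
        dv = reducer(slot, date=day)
        rows.append({"date": day, "value": dv.value, "valid": dv.valid})
    daily = pd.DataFrame(rows) if rows else pd.DataFrame(
        {"date": pd.DatetimeIndex([]), "value": [], "valid": []}
    )
    if metric == "mean":
        return annual_average(daily, schedule, site_id=site_id, pollutant=pollutant)
    return ozone_season_average(daily, site_id=site_id, pollutant=pollutant)
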