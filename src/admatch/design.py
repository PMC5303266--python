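"""Derivation of the per-day design table from a raw daily series.

The design table carries the exposure summary (lag 0-1 PM10 mean), the
binary treatment indicator, the background covariates entering the
propensity model, and the stratified death counts.  Days whose lag 0-3
temperature window extends before the series start are dropped rather than
imputed.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .strata import DEATH_COLUMNS

__all__ = ["lag_mean", "make_design", "validate_daily_series"]

#: days Dec-Feb / Mar-May / Jun-Aug / Sep-Nov
_SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF",
                    3: "MAM", 4: "MAM", 5: "MAM",
                    6: "JJA", 7: "JJA", 8: "JJA",
                    9: "SON", 10: "SON", 11: "SON"}

HEAT_THRESHOLD_C = 28.0


def lag_mean(values: Iterable[float], lags: Iterable[int]) -> np.ndarray:
    """Mean of a series over a set of backward lags.

    Element ``i`` is ``mean(values[i - l] for l in lags)``; it is NaN
    wherever any required offset precedes the start of the series.
    """
    lags = sorted(set(int(l) for l in lags))
    if not lags:
        raise ValueError("lag set must be nonempty")
    if lags[0] < 0:
        raise ValueError("lags must be nonnegative")
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    out = np.zeros_like(x)
    for l in lags:
        shifted = np.full_like(x, np.nan)
        if l == 0:
            shifted = x
        elif l < x.size:
            shifted[l:] = x[:-l]
        out = out + shifted
    return out / len(lags)


def validate_daily_series(series: pd.DataFrame) -> None:
    """Check the daily-series contract: consecutive dates, sane ranges."""
    required = {"date", "pm10", "temp", "humidity", "holiday", "influenza"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"daily series missing columns: {sorted(missing)}")
    dates = pd.to_datetime(series["date"])
    dup = dates[dates.duplicated()]
    if not dup.empty:
        raise ValueError(
            "duplicated date(s): "
            + ", ".join(str(d.date()) for d in dup.unique()))
    diffs = dates.diff().dropna()
    gaps = dates[1:][diffs != pd.Timedelta(days=1)]
    if not gaps.empty:
        missing_days = []
        prev = dates.iloc[0]
        for d in dates.iloc[1:]:
            if d - prev != pd.Timedelta(days=1):
                missing_days.extend(
                    pd.date_range(prev + pd.Timedelta(days=1), d - pd.Timedelta(days=1))
                )
            prev = d
        raise ValueError(
            "daily series has date gaps; missing: "
            + ", ".join(str(d.date()) for d in missing_days[:10])
        )
    if (series["pm10"] < 0).any():
        raise ValueError("pm10 must be >= 0")
    if ((series["humidity"] < 0) | (series["humidity"] > 100)).any():
        raise ValueError("humidity must lie in [0, 100]")
    for col in DEATH_COLUMNS:
        if col in series.columns and (series[col] < 0).any():
            raise ValueError(f"negative counts in {col}")


def make_design(series: pd.DataFrame, threshold: float = 40.0,
                heat_threshold: float = HEAT_THRESHOLD_C) -> pd.DataFrame:
    """Build the design table from a validated daily series.

    Adds: ``x`` (lag 0-1 PM10), ``w`` (1 iff ``x >= threshold``, boundary
    inclusive), ``temp03`` (lag 0-3 temperature mean), day-of-year and its
    year length, day-of-week, season, heat / July-August / weekend
    indicators, and a running calendar index.  The first three days (with
    undefined lag 0-3 temperature) are dropped; death-count columns present
    in the input are carried through unchanged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    validate_daily_series(series)
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])

    x = lag_mean(df["pm10"].to_numpy(), {0, 1})
    temp03 = lag_mean(df["temp"].to_numpy(), {0, 1, 2, 3})

    df["x"] = x
    df["w"] = (x >= threshold).astype(int)
    df["temp03"] = temp03
    df["day_of_year"] = df["date"].dt.dayofyear
    df["year_length"] = np.where(df["date"].dt.is_leap_year, 366, 365)
    df["day_of_week"] = df["date"].dt.dayofweek
    df["weekend"] = df["day_of_week"].isin([5, 6]).astype(int)
    df["season"] = df["date"].dt.month.map(_SEASON_OF_MONTH)
    df["heat"] = (df["temp03"] > heat_threshold).astype(int)
    df["julyaug"] = df["date"].dt.month.isin([7, 8]).astype(int)
    df["calendar_index"] = np.arange(len(df))

    df = df.iloc[3:].reset_index(drop=True)
    assert not df[["x", "temp03"]].isna().any().any()
    return df
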