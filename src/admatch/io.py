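"""CSV readers and writers for the canonical daily-series schema.

One flat file per series: ISO-8601 ``date``, ``pm10`` (ug/m3), ``temp``
(C), ``humidity`` (%), binary ``holiday`` and ``influenza``, and the nine
``deaths_<cause>_<age>`` count columns with cause in {cvd, resp, other} and
age in {15_64, 65_74, 75p}.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import validate_daily_series
from .simulate import GroundTruth
from .strata import DEATH_COLUMNS

__all__ = ["read_daily_csv", "write_daily_csv", "write_ground_truth_csv"]

REQUIRED_COLUMNS = ("date", "pm10", "temp", "humidity", "holiday", "influenza")


def read_daily_csv(path: str | Path, require_outcomes: bool = True) -> pd.DataFrame:
    """Read and validate a daily-series CSV.

    Validation failures (schema, date gaps or duplicates, out-of-range
    values) raise ``ValueError`` naming the offending column or date.  With
    ``require_outcomes=False`` the death-count columns may be absent, which
    supports design-phase-only runs.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if require_outcomes:
        missing = [c for c in DEATH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing death-count columns {missing}")
    bad = df["date"].isna() | pd.to_datetime(df["date"], errors="coerce").isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        raise ValueError(f"{path}: malformed date at line(s) {lines[:10]}")
    df["date"] = pd.to_datetime(df["date"])
    for col in DEATH_COLUMNS:
        if col in df.columns:
            counts = df[col]
            if not (counts == counts.round()).all():
                raise ValueError(f"{path}: non-integer counts in {col}")
            df[col] = counts.astype(int)
    validate_daily_series(df)
    return df


def write_daily_csv(series: pd.DataFrame, path: str | Path) -> None:
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    out = truth.table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
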