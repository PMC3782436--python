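"""Season-weighted averaging of the monthly Nino 3.4 index.

Season spans start and end mid-month, so a plain mean of the overlapping
monthly values would over-weight the partial months.  Each monthly value is
instead weighted by the number of season days falling inside that month
(inclusive endpoints, matching the season-duration convention), so the weights
sum exactly to the season's inclusive duration.
"""

from __future__ import annotations

import calendar
from datetime import date

import pandas as pd

from .seasons import _as_date, inclusive_duration

__all__ = ["read_monthly_index", "seasonal_nino", "month_weights"]

_MONTH_NAMES = [calendar.month_abbr[m].lower() for m in range(1, 13)]


def read_monthly_index(path) -> pd.Series:
    """Read a monthly index series from either accepted layout.

    Accepts the NOAA CPC wide layout (a year column followed by 12 monthly
    columns) or a long CSV with columns ``year,month,value``.  Returns a Series
    indexed by a monthly PeriodIndex.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if {"year", "month", "value"} <= set(df.columns):
        long = df[["year", "month", "value"]].copy()
    else:
        year_col = df.columns[0]
        month_cols = [c for c in df.columns if c in _MONTH_NAMES or c in {str(m) for m in range(1, 13)}]
        if len(month_cols) != 12:
            raise ValueError("monthly index file is neither long (year,month,value) nor wide (year + 12 months)")
        long = df.melt(id_vars=[year_col], value_vars=month_cols, var_name="month", value_name="value")
        long["month"] = long["month"].map(
            lambda m: int(m) if str(m).isdigit() else _MONTH_NAMES.index(str(m)) + 1
        )
        long = long.rename(columns={year_col: "year"})
    idx = pd.PeriodIndex.from_fields(year=long["year"].astype(int), month=long["month"].astype(int), freq="M")
    series = pd.Series(long["value"].to_numpy(float), index=idx, name="nino34").sort_index()
    if series.index.duplicated().any():
        raise ValueError("duplicate (year, month) entries in monthly index")
    return series


def month_weights(onset: date, cessation: date) -> dict[pd.Period, int]:
    """Inclusive day count of the span inside each month it touches."""
    onset = _as_date(onset)
    cessation = _as_date(cessation)
    if cessation < onset:
        raise ValueError("empty span: cessation precedes onset")
    weights: dict[pd.Period, int] = {}
    period = pd.Period(onset, freq="M")
    last = pd.Period(cessation, freq="M")
    while period <= last:
        lo = max(onset, period.start_time.date())
        hi = min(cessation, period.end_time.date())
        weights[period] = (hi - lo).days + 1
        period += 1
    assert sum(weights.values()) == inclusive_duration(onset, cessation)
    return weights


def seasonal_nino(index: pd.Series, onset: date, cessation: date) -> float:
    """Mean index value over a season span with partial months day-weighted."""
    weights = month_weights(onset, cessation)
    missing = [str(p) for p in weights if p not in index.index]
    if missing:
        raise KeyError(f"monthly index missing months: {', '.join(missing)}")
    num = sum(index[p] * w for p, w in weights.items())
    return float(num / sum(weights.values()))
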