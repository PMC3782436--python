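"""Season characterization from daily rainfall via cumulative rainfall anomalies.

A cumulative rainfall anomaly (CRA) is the running sum of daily rainfall minus a
constant daily reference rate.  Plotted against time it forms a waveform whose
annual minimum marks the transition from the dry to the wet season and whose
annual maximum marks the wet-to-dry transition: while daily rainfall runs below
the reference the curve falls, and while it runs above the curve rises.  The
descriptors derived here per season-year are onset date, cessation date,
inclusive duration, season rainfall total, and "trend consistency" -- the R^2 of
a straight line fit to the CRA inside the season, which is high when the drying
(or moistening) trend is uninterrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonWindows",
    "load_daily_csv",
    "validate_daily",
    "compute_cra",
    "inclusive_duration",
    "season_rainfall",
    "trend_consistency",
    "detect_seasons",
    "build_descriptor_table",
    "write_descriptor_table",
]


@dataclass(frozen=True)
class SeasonWindows:
    """Calendar search windows for the two wet-season boundaries.

    Defaults bracket the site's mean boundary dates (wet onset near late May,
    cessation near the start of October) with generous margins: the CRA minimum
    is searched in March-July and the maximum in August-December.
    """

    onset_start: tuple[int, int] = (3, 1)
    onset_end: tuple[int, int] = (7, 31)
    cessation_start: tuple[int, int] = (8, 1)
    cessation_end: tuple[int, int] = (12, 31)

    def onset_slice(self, year: int) -> tuple[date, date]:
        return (date(year, *self.onset_start), date(year, *self.onset_end))

    def cessation_slice(self, year: int) -> tuple[date, date]:
        return (date(year, *self.cessation_start), date(year, *self.cessation_end))


def validate_daily(series: pd.Series) -> pd.Series:
    """Validate a daily rainfall series (mm/day on a contiguous daily grid)."""
    if len(series) == 0:
        raise ValueError("empty rainfall series")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("rainfall series must be indexed by dates")
    series = series.sort_index()
    expected = pd.date_range(series.index[0], series.index[-1], freq="D")
    if len(expected) != len(series) or not series.index.equals(expected):
        raise ValueError("rainfall series has gaps or duplicates in its daily grid")
    if series.isna().any():
        raise ValueError("rainfall series contains missing values")
    if (series < 0).any():
        bad = series.index[series < 0][0].date()
        raise ValueError(f"negative rainfall at {bad}")
    return series


def load_daily_csv(path) -> pd.Series:
    """Read a ``date,rain_mm`` CSV (ISO-8601 dates) into a daily series."""
    df = pd.read_csv(path, parse_dates=["date"])
    if "rain_mm" not in df.columns:
        raise ValueError("daily rainfall CSV must have columns date,rain_mm")
    series = pd.Series(df["rain_mm"].to_numpy(float), index=pd.DatetimeIndex(df["date"]), name="rain_mm")
    return validate_daily(series)


def compute_cra(series: pd.Series, reference="long-term-mean", smooth_days: int | None = None) -> pd.Series:
    """Cumulative rainfall anomaly: running sum of (rainfall - reference rate).

    Parameters
    ----------
    series
        Daily rainfall, mm/day, contiguous daily grid.
    reference
        Constant daily reference rate in mm/day, or ``"long-term-mean"`` to use
        the series' own full-record mean (in which case the final CRA value is
        zero by telescoping).
    smooth_days
        Optional centered moving-average window applied to the CRA, off by
        default.
    """
    series = validate_daily(series)
    if reference == "long-term-mean":
        ref = float(series.mean())
    else:
        ref = float(reference)
        if ref <= 0:
            raise ValueError("reference rate must be strictly positive")
    cra = (series - ref).cumsum()
    cra.name = "cra"
    if smooth_days is not None:
        if smooth_days < 1:
            raise ValueError("smoothing window must be >= 1 day")
        cra = cra.rolling(smooth_days, center=True, min_periods=1).mean()
        cra.name = "cra"
    return cra


def inclusive_duration(onset: date, cessation: date) -> int:
    """Day count from onset to cessation with both endpoint days counted.

    The convention is anchored by the site's mean seasons: May 21 - Oct 1 spans
    134 days and Oct 2 - May 20 of the next year spans 231 days.  Spans crossing
    New Year are handled by the actual calendar difference.
    """
    onset = _as_date(onset)
    cessation = _as_date(cessation)
    delta = (cessation - onset).days
    if delta < 0:
        raise ValueError(f"cessation {cessation} precedes onset {onset}")
    return delta + 1


def season_rainfall(series: pd.Series, onset: date, cessation: date) -> float:
    """Total rainfall over the inclusive span, in cm."""
    series = validate_daily(series)
    onset_ts, cess_ts = pd.Timestamp(_as_date(onset)), pd.Timestamp(_as_date(cessation))
    if onset_ts < series.index[0] or cess_ts > series.index[-1]:
        raise ValueError("season span extends outside the rainfall record")
    if cess_ts < onset_ts:
        raise ValueError("cessation precedes onset")
    return float(series.loc[onset_ts:cess_ts].sum()) / 10.0


def trend_consistency(cra: pd.Series, onset: date, cessation: date) -> float:
    """R^2 of an OLS line fit to the CRA against day index within the season.

    Returns NaN (a flagged failure, not a crash) if the CRA segment has zero
    variance; raises if the span has fewer than 3 days.
    """
    onset_ts, cess_ts = pd.Timestamp(_as_date(onset)), pd.Timestamp(_as_date(cessation))
    seg = cra.loc[onset_ts:cess_ts].to_numpy(float)
    if len(seg) < 3:
        raise ValueError("trend consistency needs a span of at least 3 days")
    y = seg - seg.mean()
    sst = float(y @ y)
    if sst <= 1e-12:
        return float("nan")
    x = np.arange(len(seg), dtype=float)
    x = x - x.mean()
    slope = float(x @ y) / float(x @ x)
    resid = y - slope * x
    r2 = 1.0 - float(resid @ resid) / sst
    # guard tiny negative rounding
    return float(min(max(r2, 0.0), 1.0))


@dataclass
class SeasonBoundaries:
    """Detected wet-season boundaries for one calendar year."""

    year: int
    wet_onset: date | None
    wet_cessation: date | None
    ok: bool
    reason: str = ""


def detect_seasons(
    cra: pd.Series,
    windows: SeasonWindows = SeasonWindows(),
    flat_tol: float = 1e-9,
) -> list[SeasonBoundaries]:
    """Locate per-year wet-season boundaries from the CRA waveform.

    Wet onset is the day after the CRA minimum inside the onset window (the
    turning point where the anomaly stops falling and begins its sustained
    rise); cessation is the day of the CRA maximum inside the cessation window.
    Years whose windowed CRA is flat (no turning point, e.g. constant rainfall)
    are flagged rather than raising.  Ties go to the earliest day.
    """
    if not isinstance(cra.index, pd.DatetimeIndex):
        raise TypeError("CRA series must be date-indexed")
    years = range(cra.index[0].year, cra.index[-1].year + 1)
    out: list[SeasonBoundaries] = []
    for year in years:
        on_lo, on_hi = windows.onset_slice(year)
        ce_lo, ce_hi = windows.cessation_slice(year)
        if pd.Timestamp(on_lo) < cra.index[0] or pd.Timestamp(ce_hi) > cra.index[-1]:
            out.append(SeasonBoundaries(year, None, None, False, "window outside record"))
            continue
        on_seg = cra.loc[pd.Timestamp(on_lo):pd.Timestamp(on_hi)]
        ce_seg = cra.loc[pd.Timestamp(ce_lo):pd.Timestamp(ce_hi)]
        if on_seg.max() - on_seg.min() <= flat_tol or ce_seg.max() - ce_seg.min() <= flat_tol:
            out.append(SeasonBoundaries(year, None, None, False, "no turning point (flat CRA)"))
            continue
        min_day, max_day = on_seg.idxmin(), ce_seg.idxmax()
        # an extremum on the window boundary is not a turning point: the CRA
        # was still falling (or rising) when the window closed
        if min_day in (on_seg.index[0], on_seg.index[-1]) or max_day in (ce_seg.index[0], ce_seg.index[-1]):
            out.append(SeasonBoundaries(year, None, None, False, "no turning point (extremum at window edge)"))
            continue
        onset = (min_day + timedelta(days=1)).date()
        cessation = max_day.date()
        out.append(SeasonBoundaries(year, onset, cessation, True))
    return out


def build_descriptor_table(
    series: pd.Series,
    years: range | None = None,
    windows: SeasonWindows = SeasonWindows(),
    reference="long-term-mean",
) -> pd.DataFrame:
    """One wet and one dry descriptor row per season-year.

    The wet season runs from the detected onset to the detected cessation; the
    dry season is the complement, starting the day after wet cessation and
    ending the day before the next year's wet onset (so it spans New Year and is
    labeled by the calendar year of its onset; the record's final year
    therefore has no complete dry season).  Rows for years with detection
    failures are flagged ``ok=False`` and carry NaN descriptors; a count is
    logged so downstream exclusion is visible.
    """
    series = validate_daily(series)
    cra = compute_cra(series, reference=reference)
    bounds = {b.year: b for b in detect_seasons(cra, windows=windows)}
    if years is None:
        years = range(min(bounds), max(bounds) + 1)

    rows = []
    n_failed = 0
    for year in years:
        b = bounds.get(year)
        if b is None or not b.ok:
            n_failed += 1
            rows.append(_failed_row(year, "wet", b.reason if b else "year outside record"))
        else:
            rows.append(_season_row(series, cra, year, "wet", b.wet_onset, b.wet_cessation))
        # dry season of `year` needs the following year's wet onset
        nxt = bounds.get(year + 1)
        if b is None or not b.ok or nxt is None or not nxt.ok:
            if year + 1 in bounds or (b is not None and not b.ok):
                n_failed += 1
                rows.append(_failed_row(year, "dry", "boundary year failed or record ends"))
            continue
        dry_onset = b.wet_cessation + timedelta(days=1)
        dry_cess = nxt.wet_onset - timedelta(days=1)
        rows.append(_season_row(series, cra, year, "dry", dry_onset, dry_cess))
    if n_failed:
        logger.info("descriptor table: %d season rows flagged as detection failures", n_failed)
    df = pd.DataFrame(rows)
    return df


def _season_row(series, cra, year, season, onset, cessation):
    return {
        "year": year,
        "season": season,
        "onset": onset,
        "cessation": cessation,
        "onset_doy": onset.timetuple().tm_yday,
        "cessation_doy": cessation.timetuple().tm_yday,
        "duration_days": inclusive_duration(onset, cessation),
        "rainfall_cm": season_rainfall(series, onset, cessation),
        "trend_r2": trend_consistency(cra, onset, cessation),
        "ok": True,
        "reason": "",
    }


def _failed_row(year, season, reason):
    return {
        "year": year,
        "season": season,
        "onset": None,
        "cessation": None,
        "onset_doy": np.nan,
        "cessation_doy": np.nan,
        "duration_days": np.nan,
        "rainfall_cm": np.nan,
        "trend_r2": np.nan,
        "ok": False,
        "reason": reason,
    }


def write_descriptor_table(df: pd.DataFrame, path) -> None:
    """Emit the descriptor table as TSV."""
    cols = ["year", "season", "onset", "cessation", "duration_days", "rainfall_cm", "trend_r2", "ok", "reason"]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def _as_date(d) -> date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, date):
        return d
    return pd.Timestamp(d).date()
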