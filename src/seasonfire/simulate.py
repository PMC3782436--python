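"""Synthetic inputs with known ground truth.

Two generation levels serve different tests:

* descriptor level -- exact linear-Gaussian draws from a fully specified path
  model, so the SEM engine is exercised without season-detection noise;
* daily level -- a mechanistic rainfall/ENSO generator with a known season
  calendar, so the CRA season detector is exercised against stored truth.

The daily generator switches a stochastic storm process (Bernoulli wet days
with gamma-distributed depths) between wet and dry rate regimes at jittered
boundary dates, modulates each dry season's rate by an AR(1) monthly ENSO
index, and rescales each season-year by a lognormal multiplier to give the
interannual spread seen in subtropical Florida records (dry seasons around
42 +/- 15 cm, wet around 89 +/- 27 cm, boundary dates jittering with SDs near
one month).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, load_entry
from .sem import PathModel

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateGenConfig",
    "FireGenConfig",
    "standardized_implied_corr",
    "sample_from_path_model",
    "generate_daily_climate",
    "generate_fire_records",
]


# ---------------------------------------------------------------------------
# Descriptor-level sampling
# ---------------------------------------------------------------------------


def standardized_implied_corr(model: PathModel) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma, error variances) for a fully fixed standardized model.

    Exogenous variables get unit variance and zero covariance; each endogenous
    error variance is set to 1 minus the variance explained by its parents, so
    every variable has unit implied variance and the coefficients are
    simultaneously raw and standardized.
    """
    A = model.coefficient_matrix()
    p = model.p
    idx = {v: i for i, v in enumerate(model.variables)}
    sigma = np.zeros((p, p))
    errvar = np.zeros(p)
    for v in model.exogenous:
        i = idx[v]
        sigma[i, i] = 1.0
        errvar[i] = 1.0
    for v in model.topological_order():
        i = idx[v]
        if v in model.exogenous:
            continue
        a = A[i, :]
        explained = float(a @ sigma @ a)
        if explained >= 1.0:
            raise ValueError(
                f"{model.name or 'model'}: parents of {v!r} explain {explained:.3f} >= 1 "
                "of its unit variance; coefficients inconsistent with standardization"
            )
        errvar[i] = 1.0 - explained
        cov_row = sigma @ a  # cov of v with every earlier variable
        sigma[i, :] = cov_row
        sigma[:, i] = cov_row
        sigma[i, i] = 1.0
    return sigma, errvar


def sample_from_path_model(entry, n: int, seed: int) -> pd.DataFrame:
    """n multivariate-normal rows whose population covariance is the model's
    standardized implied covariance; reproducible under seed."""
    model = entry.model if isinstance(entry, CatalogEntry) else entry
    if isinstance(entry, str):
        model = load_entry(entry).model
    if not model.fully_fixed():
        raise ValueError("sample_from_path_model needs every coefficient fixed")
    A = model.coefficient_matrix()
    _, errvar = standardized_implied_corr(model)
    rng = np.random.default_rng(seed)
    p = model.p
    e = rng.standard_normal((n, p)) * np.sqrt(errvar)
    # z = A z + e solved in topological order
    idx = {v: i for i, v in enumerate(model.variables)}
    z = np.zeros((n, p))
    for v in model.topological_order():
        i = idx[v]
        z[:, i] = z @ A[i, :] + e[:, i]
    return pd.DataFrame(z, columns=model.variables)


# ---------------------------------------------------------------------------
# Daily-level mechanistic climate generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateGenConfig:
    """Defaults emulate the study site's 58-year climatology."""

    start_year: int = 1950
    years: int = 58
    wet_onset_doy: int = 141      # May 21 (non-leap)
    wet_cessation_doy: int = 274  # Oct 1
    onset_sd_days: float = 30.0   # boundary jitter, "almost one month"
    cessation_sd_days: float = 30.0
    max_jitter_days: int = 60     # keep truth inside the detection windows
    wet_rate_mm: float = 6.64     # 89 cm over a 134-day season
    dry_rate_mm: float = 1.82     # 42 cm over a 231-day season
    wet_day_prob: float = 0.95    # in-season rain falls most days, lightly
    dry_day_prob: float = 0.60
    gamma_shape: float = 3.0      # storm-depth shape (moderate daily skew)
    wet_year_sigma: float = 0.15  # lognormal interannual multiplier, wet
    dry_year_sigma: float = 0.12  # residual interannual multiplier, dry
    enso_coupling: float = 0.20   # d(log dry rate)/d(seasonal Nino 3.4)
    enso_ar1: float = 0.92        # monthly AR(1) coefficient
    enso_sd: float = 0.9          # marginal index SD, deg C
    seed: int = 0

    def validate(self) -> None:
        if self.wet_rate_mm <= 0 or self.dry_rate_mm <= 0:
            raise ValueError("rain rates must be positive")
        if not 0 < self.enso_ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (0, 1)")
        if not (0 < self.wet_day_prob <= 1 and 0 < self.dry_day_prob <= 1):
            raise ValueError("storm-day probabilities must lie in (0, 1]")
        if self.years < 1:
            raise ValueError("need at least one year")


def _ar1_monthly(config: ClimateGenConfig, rng, n_months: int) -> np.ndarray:
    phi = config.enso_ar1
    innov_sd = config.enso_sd * np.sqrt(1 - phi * phi)
    x = np.empty(n_months)
    x[0] = rng.normal(0.0, config.enso_sd)
    shocks = rng.normal(0.0, innov_sd, n_months)
    for t in range(1, n_months):
        x[t] = phi * x[t - 1] + shocks[t]
    return x


def generate_daily_climate(config: ClimateGenConfig = ClimateGenConfig()):
    """Daily rainfall + monthly ENSO index + ground-truth season calendar.

    Returns ``(rain, nino, truth)``: a daily mm series spanning whole calendar
    years, a monthly PeriodIndex series, and a DataFrame of the true per-year
    wet onset/cessation dates actually used (the seed is recorded in
    ``truth.attrs``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, ny = config.start_year, config.years
    index = pd.date_range(date(y0, 1, 1), date(y0 + ny - 1, 12, 31), freq="D")
    n_days = len(index)

    months = pd.period_range(f"{y0}-01", f"{y0 + ny - 1}-12", freq="M")
    nino = pd.Series(_ar1_monthly(config, rng, len(months)), index=months, name="nino34")

    # ground-truth boundaries, jitter clipped inside the search windows
    years = np.arange(y0, y0 + ny)
    onset_jit = np.clip(rng.normal(0, config.onset_sd_days, ny), -config.max_jitter_days, config.max_jitter_days)
    cess_jit = np.clip(rng.normal(0, config.cessation_sd_days, ny), -config.max_jitter_days, config.max_jitter_days)
    truth_rows = []
    for k, year in enumerate(years):
        onset = date(year, 1, 1) + timedelta(days=config.wet_onset_doy - 1 + int(round(onset_jit[k])))
        cess = date(year, 1, 1) + timedelta(days=config.wet_cessation_doy - 1 + int(round(cess_jit[k])))
        truth_rows.append({"year": year, "wet_onset": onset, "wet_cessation": cess})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = config.seed

    # per-day season membership from the truth calendar
    onset_ts = pd.DatetimeIndex([pd.Timestamp(r["wet_onset"]) for r in truth_rows])
    cess_ts = pd.DatetimeIndex([pd.Timestamp(r["wet_cessation"]) for r in truth_rows])
    is_wet = np.zeros(n_days, dtype=bool)
    for on, ce in zip(onset_ts, cess_ts):
        is_wet |= (index >= on) & (index <= ce)

    # dry-season-year label: the calendar year whose wet cessation starts it
    # (days before year k's onset belong to dry season k-1)
    day_year = index.year.to_numpy()
    dry_year = day_year.copy()
    for k, year in enumerate(years):
        before_onset = (day_year == year) & (index < onset_ts[k])
        dry_year[before_onset] = year - 1

    # interannual rate multipliers, log-clipped at +-2 SD: the wettest dry
    # season must stay clearly below the annual-mean rate or the CRA loses its
    # turning points (observed dry-season totals never approach that limit)
    ws = config.wet_year_sigma
    wet_mult = {
        year: np.exp(np.clip(rng.normal(0, ws), -2 * ws, 2 * ws) - ws**2 / 2) for year in years
    }
    dry_mult = {}
    tot_sd = np.sqrt((config.enso_coupling * config.enso_sd) ** 2 + config.dry_year_sigma**2)
    for k, year in enumerate(years):
        month_lo = pd.Period(cess_ts[k], freq="M")
        month_hi = pd.Period(onset_ts[k + 1] if k + 1 < ny else pd.Timestamp(date(year, 12, 31)), freq="M")
        sel = (nino.index >= month_lo) & (nino.index <= month_hi)
        seasonal = float(nino[sel].mean()) if sel.any() else 0.0
        lg = config.enso_coupling * seasonal + rng.normal(0, config.dry_year_sigma)
        dry_mult[year] = np.exp(np.clip(lg, -2 * tot_sd, 2 * tot_sd) - tot_sd**2 / 2)
    # leading dry stub of the first year inherits its own year's multiplier
    dry_mult[years[0] - 1] = dry_mult[years[0]]

    p = np.where(is_wet, config.wet_day_prob, config.dry_day_prob)
    base_rate = np.where(is_wet, config.wet_rate_mm, config.dry_rate_mm)
    year_key = np.where(is_wet, day_year, dry_year)
    mult = np.where(
        is_wet,
        np.array([wet_mult.get(y, 1.0) for y in year_key]),
        np.array([dry_mult.get(y, 1.0) for y in year_key]),
    )
    mean_depth = base_rate * mult / p
    wet_day = rng.random(n_days) < p
    depths = rng.gamma(config.gamma_shape, mean_depth / config.gamma_shape)
    rain = pd.Series(np.where(wet_day, depths, 0.0), index=index, name="rain_mm")
    return rain, nino, truth


# ---------------------------------------------------------------------------
# Fire records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FireGenConfig:
    """Fire-regime generator driven by the second-best wildfire path model.

    Coefficients act on standardized sqrt-scale variables; location/scale
    constants place the back-transformed records near the site's magnitudes
    (about 13 wildfires and 2,000 ha burned in a typical year).
    """

    coef_tc_wet_n_fires: float = -0.52
    coef_rain_n_fires: float = 0.0
    coef_rain_area: float = -0.51
    coef_n_fires_area: float = 0.51
    coef_tc_wet_area: float = 0.0
    coef_nino_area: float = 0.0
    n_fires_noise_sd: float = 0.854   # sqrt(1 - 0.27): published R^2 for counts
    area_noise_sd: float = 0.61      # sqrt(1 - 0.63): published R^2 for area
    sqrt_n_fires_mean: float = 3.5
    sqrt_n_fires_scale: float = 1.0
    sqrt_area_mean: float = 40.0
    sqrt_area_scale: float = 15.0
    seed: int = 0


def generate_fire_records(descriptors: pd.DataFrame, config: FireGenConfig = FireGenConfig()) -> pd.DataFrame:
    """Annual fire counts and area burned driven by the configured path model.

    ``descriptors`` needs columns ``year``, ``rain_dry`` (cm), ``tc_wet``
    (previous wet season's trend consistency, already lagged) and optionally
    ``nino`` (dry-season index).  Drivers are standardized within sample; the
    linear model runs on the sqrt scale, is back-transformed, counts rounded,
    and negatives truncated at zero with a logged count.
    """
    required = {"year", "rain_dry", "tc_wet"}
    missing = required - set(descriptors.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    z_rain = _zscore(descriptors["rain_dry"].to_numpy(float))
    z_tcw = _zscore(descriptors["tc_wet"].to_numpy(float))
    z_nino = (
        _zscore(descriptors["nino"].to_numpy(float)) if "nino" in descriptors.columns else np.zeros(len(descriptors))
    )
    n = len(descriptors)

    z_nf = (
        config.coef_tc_wet_n_fires * z_tcw
        + config.coef_rain_n_fires * z_rain
        + rng.normal(0, config.n_fires_noise_sd, n)
    )
    z_area = (
        config.coef_rain_area * z_rain
        + config.coef_n_fires_area * z_nf
        + config.coef_tc_wet_area * z_tcw
        + config.coef_nino_area * z_nino
        + rng.normal(0, config.area_noise_sd, n)
    )

    sqrt_nf = config.sqrt_n_fires_mean + config.sqrt_n_fires_scale * z_nf
    sqrt_area = config.sqrt_area_mean + config.sqrt_area_scale * z_area
    truncated = int(np.sum(sqrt_nf < 0) + np.sum(sqrt_area < 0))
    if truncated:
        logger.info("fire generator: %d sqrt-scale values truncated at zero", truncated)
    n_fires = np.round(np.maximum(sqrt_nf, 0.0) ** 2).astype(int)
    area = np.maximum(sqrt_area, 0.0) ** 2
    out = pd.DataFrame({"year": descriptors["year"].to_numpy(), "n_fires": n_fires, "area_burned": area})
    out.attrs["seed"] = config.seed
    out.attrs["truncated"] = truncated
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate driver column (zero variance)")
    return (x - x.mean()) / sd
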