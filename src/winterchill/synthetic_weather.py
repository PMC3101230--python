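"""Stochastic daily weather generator and synthetic-site factory.

The generator follows the classic site-parameter design of stochastic
weather generators: temperatures are a smooth seasonal climatology (monthly
means, linearly interpolated between mid-month anchors so the seasonal cycle
has no step discontinuities) plus AR(1) lag-1 autocorrelated standardized
residuals, with Tmax residuals cross-correlated with Tmin residuals;
precipitation occurrence is a two-state first-order Markov chain with
per-month transition probabilities, and wet-day amounts are gamma
distributed.  A :class:`~winterchill.scenarios.ClimateScenario` perturbs
generation: temperature deltas are added to the corresponding month's mean
(as a per-month step, so a single-month anomaly passes through undiluted)
and precipitation amounts are scaled by the monthly factor.

Calibration estimates all site parameters from an observed daily record;
``synthetic_site_params`` fabricates plausible parameters for a site from
latitude and mean annual temperature, which is how the test fixtures and
the toy worlds are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import ClimateScenario

logger = logging.getLogger(__name__)

WET_THRESHOLD_MM = 0.1  # a day is wet when prcp exceeds this
SD_FLOOR_C = 0.1  # replaces degenerate (zero) monthly temperature sds

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_DOY = np.cumsum(_DAYS_IN_MONTH) - _DAYS_IN_MONTH / 2.0  # mid-month day of a 365-day year

_ARRAY_FIELDS = [
    "monthly_mean_tmin", "monthly_mean_tmax", "monthly_sd_tmin", "monthly_sd_tmax",
    "p_wet_given_wet", "p_wet_given_dry", "gamma_shape", "gamma_scale",
]


@dataclass
class GeneratorParams:
    """Site parameters of the daily weather generator (index 0 = January)."""

    monthly_mean_tmin: np.ndarray
    monthly_mean_tmax: np.ndarray
    monthly_sd_tmin: np.ndarray
    monthly_sd_tmax: np.ndarray
    lag1_autocorr: float
    cross_corr_minmax: float
    p_wet_given_wet: np.ndarray
    p_wet_given_dry: np.ndarray
    gamma_shape: np.ndarray
    gamma_scale: np.ndarray

    def __post_init__(self):
        for name in _ARRAY_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 values")
            setattr(self, name, arr)
        if not -1 < self.lag1_autocorr < 1:
            raise ValueError("lag1_autocorr must lie in (-1, 1)")
        if not -1 < self.cross_corr_minmax < 1:
            raise ValueError("cross_corr_minmax must lie in (-1, 1)")
        for p in (self.p_wet_given_wet, self.p_wet_given_dry):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(self.monthly_sd_tmin <= 0) or np.any(self.monthly_sd_tmax <= 0):
            raise ValueError("monthly temperature sds must be > 0")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"lag1_autocorr = {float(self.lag1_autocorr)!r}\n")
            fh.write(f"cross_corr_minmax = {float(self.cross_corr_minmax)!r}\n")
            for name in _ARRAY_FIELDS:
                vals = ",".join(repr(float(v)) for v in getattr(self, name))
                fh.write(f"{name} = {vals}\n")

    @classmethod
    def from_text(cls, path) -> "GeneratorParams":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        kwargs = {
            "lag1_autocorr": float(kv["lag1_autocorr"]),
            "cross_corr_minmax": float(kv["cross_corr_minmax"]),
        }
        for name in _ARRAY_FIELDS:
            kwargs[name] = np.array([float(v) for v in kv[name].split(",")])
        return cls(**kwargs)


@dataclass
class SyntheticSeries:
    """A generated daily series for one station under one scenario."""

    station_id: str
    scenario_label: str
    days: pd.DataFrame  # columns date, tmin, tmax, prcp
    seed: int
    n_clamped: int = 0  # days where tmax had to be lifted to tmin


def _clip_corr(r: float) -> float:
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(r, -0.99, 0.99))


def calibrate(records: pd.DataFrame) -> GeneratorParams:
    """Estimate site parameters from an observed daily record (>= 5 years).

    Monthly moments are sample statistics (zero sds are floored at
    ``SD_FLOOR_C``); the lag-1 autocorrelation comes from deseasonalized Tmin
    residuals; Markov transition probabilities from wet/dry day transition
    counts; gamma parameters by method of moments on wet-day amounts.
    """
    df = records.sort_values("date").reset_index(drop=True)
    n_years = df["date"].dt.year.nunique()
    if n_years < 5:
        raise ValueError(f"calibration needs >= 5 years of records, got {n_years}")
    month = df["date"].dt.month

    mean_tmin = np.full(12, np.nan)
    mean_tmax = np.full(12, np.nan)
    sd_tmin = np.full(12, np.nan)
    sd_tmax = np.full(12, np.nan)
    for m in range(1, 13):
        sel = month == m
        mean_tmin[m - 1] = df.loc[sel, "tmin"].mean()
        mean_tmax[m - 1] = df.loc[sel, "tmax"].mean()
        sd_tmin[m - 1] = df.loc[sel, "tmin"].std()
        sd_tmax[m - 1] = df.loc[sel, "tmax"].std()
    for name, sd in (("tmin", sd_tmin), ("tmax", sd_tmax)):
        degen = ~np.isfinite(sd) | (sd < SD_FLOOR_C)
        if degen.any():
            logger.warning("degenerate %s sd in month(s) %s; floored at %.1f °C",
                           name, list(np.where(degen)[0] + 1), SD_FLOOR_C)
            sd[degen] = SD_FLOOR_C

    # lag-1 autocorrelation of deseasonalized tmin; cross-corr of residuals
    resid_min = df["tmin"] - mean_tmin[month - 1]
    resid_max = df["tmax"] - mean_tmax[month - 1]
    consecutive = df["date"].diff().dt.days == 1
    def _corr(a, b) -> float:
        if len(a) < 30 or np.std(a) < 1e-12 or np.std(b) < 1e-12:
            return 0.0
        return _clip_corr(np.corrcoef(a, b)[0, 1])

    ok = resid_min.notna() & resid_min.shift(1).notna() & consecutive
    rho = _corr(resid_min[ok].to_numpy(), resid_min.shift(1)[ok].to_numpy())
    both = resid_min.notna() & resid_max.notna()
    cross = _corr(resid_min[both].to_numpy(), resid_max[both].to_numpy())

    # precipitation occurrence and amounts
    wet = df["prcp"] > WET_THRESHOLD_MM
    known = df["prcp"].notna()
    p_ww = np.zeros(12)
    p_wd = np.zeros(12)
    shape = np.full(12, np.nan)
    scale = np.full(12, np.nan)
    prev_wet = wet.shift(1, fill_value=False)
    trans_ok = consecutive & known & known.shift(1, fill_value=False)
    for m in range(1, 13):
        sel = (month == m) & trans_ok
        from_wet = sel & prev_wet
        from_dry = sel & ~prev_wet
        if from_wet.sum() > 0:
            p_ww[m - 1] = wet[from_wet].mean()
        if from_dry.sum() > 0:
            p_wd[m - 1] = wet[from_dry].mean()
        amounts = df.loc[(month == m) & wet, "prcp"]
        if len(amounts) == 0:
            logger.warning("month %d has no wet days; gamma parameters degenerate", m)
            continue
        mu, var = amounts.mean(), amounts.var()
        if len(amounts) < 2 or not np.isfinite(var) or var < 1e-12:
            shape[m - 1] = 1.0  # exponential fallback with the observed mean
            scale[m - 1] = mu
        else:
            shape[m - 1] = mu**2 / var
            scale[m - 1] = var / mu
    return GeneratorParams(
        monthly_mean_tmin=mean_tmin, monthly_mean_tmax=mean_tmax,
        monthly_sd_tmin=sd_tmin, monthly_sd_tmax=sd_tmax,
        lag1_autocorr=rho, cross_corr_minmax=cross,
        p_wet_given_wet=p_ww, p_wet_given_dry=p_wd,
        gamma_shape=shape, gamma_scale=scale,
    )


def _interp_daily(monthly: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Mid-month anchored periodic linear interpolation of a monthly climatology."""
    xs = np.concatenate(([_MID_DOY[-1] - 365.0], _MID_DOY, [_MID_DOY[0] + 365.0]))
    ys = np.concatenate(([monthly[-1]], monthly, [monthly[0]]))
    return np.interp(doy, xs, ys)


def _monthly_mean_operator() -> np.ndarray:
    """Matrix mapping mid-month anchor values to the monthly means of the
    interpolated daily climatology (piecewise-linear interpolation pulls
    monthly averages toward neighbouring months)."""
    doy = np.arange(1, 366, dtype=float)
    month_of_doy = np.searchsorted(np.cumsum(_DAYS_IN_MONTH), doy - 0.5)
    W = np.empty((12, 12))
    for j in range(12):
        e = np.zeros(12)
        e[j] = 1.0
        daily = _interp_daily(e, doy)
        W[:, j] = np.bincount(month_of_doy, weights=daily, minlength=12) / _DAYS_IN_MONTH
    return W


_W_MONTHLY = _monthly_mean_operator()
_W_INV = np.linalg.inv(_W_MONTHLY)


def _mean_preserving_anchors(monthly: np.ndarray) -> np.ndarray:
    """Anchor values whose interpolated daily series averages back to the
    requested monthly means (mean-preserving smooth climatology)."""
    return _W_INV @ monthly


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + c * eps[t]
    return z


def generate(
    params: GeneratorParams,
    scenario: ClimateScenario | None = None,
    n_years: int = 101,
    seed: int = 0,
    station_id: str = "synthetic",
    start_year: int = 2000,
) -> SyntheticSeries:
    """Generate ``n_years`` calendar years of daily weather under a scenario.

    Deterministic given (params, scenario, n_years, seed): the single seed is
    expanded into independent substreams for the Tmin residual, the Tmax
    residual, and precipitation.  ``tmax >= tmin`` is enforced by clamping
    (the number of clamped days is reported on the result).
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2 (a winter spans two calendar years)")
    scenario = scenario or ClimateScenario.zero()
    ss = np.random.SeedSequence(seed)
    rng_min, rng_max, rng_prcp = (np.random.default_rng(s) for s in ss.spawn(3))

    if start_year + n_years > 2250:  # keep timestamps inside pandas' ns range
        start_year = 2250 - n_years
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = np.minimum(dates.dayofyear.to_numpy(), 365).astype(float)
    midx = dates.month.to_numpy() - 1

    anchors_tmin = _mean_preserving_anchors(params.monthly_mean_tmin)
    anchors_tmax = _mean_preserving_anchors(params.monthly_mean_tmax)
    base_tmin = _interp_daily(anchors_tmin, doy) + scenario.delta_tmin[midx]
    base_tmax = _interp_daily(anchors_tmax, doy) + scenario.delta_tmax[midx]

    rho = params.lag1_autocorr
    z = _ar1(rng_min, n, rho)
    u = _ar1(rng_max, n, rho)
    c = params.cross_corr_minmax
    w = c * z + np.sqrt(1.0 - c * c) * u
    tmin = base_tmin + params.monthly_sd_tmin[midx] * z
    tmax = base_tmax + params.monthly_sd_tmax[midx] * w

    clamped = tmax < tmin
    n_clamped = int(clamped.sum())
    tmax = np.maximum(tmax, tmin)

    # Markov occurrence then gamma amounts scaled by the scenario factor
    occ_u = rng_prcp.random(n)
    wet = np.zeros(n, dtype=bool)
    p_ww, p_wd = params.p_wet_given_wet, params.p_wet_given_dry
    prev = False
    for t in range(n):
        p = p_ww[midx[t]] if prev else p_wd[midx[t]]
        prev = occ_u[t] < p
        wet[t] = prev
    prcp = np.zeros(n)
    shape_d = params.gamma_shape[midx]
    scale_d = params.gamma_scale[midx]
    usable = wet & np.isfinite(shape_d) & np.isfinite(scale_d)
    k = int(usable.sum())
    if k:
        prcp[usable] = rng_prcp.gamma(shape_d[usable], scale_d[usable])
        prcp[usable] *= scenario.precip_factor[midx[usable]]

    days = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax, "prcp": prcp})
    if n_clamped:
        logger.debug("%d generated day(s) clamped to tmax >= tmin", n_clamped)
    return SyntheticSeries(station_id, scenario.label, days, seed, n_clamped)


def synthetic_site_params(
    latitude: float,
    mean_annual_temp: float,
    seed: int = 0,
    diurnal_range: float = 8.0,
    wetness: float = 0.35,
) -> GeneratorParams:
    """Fabricate plausible generator parameters for a site.

    The seasonal cycle is a sinusoid whose amplitude grows with |latitude|
    (~0.35 °C per degree, phase set by hemisphere), centred on the requested
    mean annual temperature; day-to-day variability, persistence and rain
    statistics are typical mid-latitude values with mild random jitter.
    """
    rng = np.random.default_rng(seed)
    amp = 2.0 + 0.35 * abs(latitude)
    phase = 0.0 if latitude >= 0 else np.pi  # coldest in Jan (NH) / Jul (SH)
    m = np.arange(12)
    seasonal = -amp * np.cos(2 * np.pi * (m - 0.5) / 12.0 + phase)
    tmean = mean_annual_temp + seasonal
    mean_tmin = tmean - diurnal_range / 2.0
    mean_tmax = tmean + diurnal_range / 2.0
    sd = 2.5 + rng.uniform(-0.3, 0.3, 12)
    p_wd = np.clip(wetness * 0.8 + rng.uniform(-0.05, 0.05, 12), 0.02, 0.95)
    p_ww = np.clip(p_wd + 0.25, 0.05, 0.95)
    return GeneratorParams(
        monthly_mean_tmin=mean_tmin, monthly_mean_tmax=mean_tmax,
        monthly_sd_tmin=sd, monthly_sd_tmax=sd * (1 + rng.uniform(0, 0.2, 12)),
        lag1_autocorr=0.65, cross_corr_minmax=0.6,
        p_wet_given_wet=p_ww, p_wet_given_dry=p_wd,
        gamma_shape=np.full(12, 0.9), gamma_scale=np.full(12, 6.0),
    )
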