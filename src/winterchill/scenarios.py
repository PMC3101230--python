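"""Climate scenario construction.

Two kinds of scenarios drive the weather generator:

* *baseline trend scenarios* ("typical conditions in year Y"): for every
  station and calendar month, ordinary least squares of the monthly mean
  minimum/maximum temperature (and monthly precipitation total) against the
  calendar year over a calibration window; the scenario for a target year is
  the trend prediction at that year expressed as an anomaly from the
  calibration-period monthly mean.
* *anomaly-table scenarios*: 12-month ΔTmin/ΔTmax (°C, additive) and
  precipitation factors (multiplicative) per labelled future world
  (epoch × emissions pathway × climate model), read from CSV.

Temperature anomalies are additive and precipitation anomalies
multiplicative, which keeps generated precipitation non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTHS = np.arange(1, 13)


@dataclass
class ClimateScenario:
    """A 12-month perturbation of a station's calibration climate."""

    label: str
    delta_tmin: np.ndarray  # °C, additive, index 0 = January
    delta_tmax: np.ndarray
    precip_factor: np.ndarray  # multiplicative, >= 0
    epoch: str = "past"
    ghg: str = ""
    gcm: str = ""

    def __post_init__(self):
        self.delta_tmin = np.asarray(self.delta_tmin, dtype=float)
        self.delta_tmax = np.asarray(self.delta_tmax, dtype=float)
        self.precip_factor = np.asarray(self.precip_factor, dtype=float)
        for name in ("delta_tmin", "delta_tmax", "precip_factor"):
            arr = getattr(self, name)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values, got {arr.shape}")
        if not np.all(np.isfinite(self.precip_factor)) or np.any(self.precip_factor < 0):
            raise ValueError("precip_factor must be finite and >= 0")

    @classmethod
    def zero(cls, label: str = "baseline") -> "ClimateScenario":
        return cls(label, np.zeros(12), np.zeros(12), np.ones(12))


def monthly_aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Monthly means of tmin/tmax and monthly precipitation totals.

    A month whose variable has more than 50% of its calendar days missing
    yields a missing aggregate for that variable.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["station_id", "year", "month", "mean_tmin", "mean_tmax", "total_prcp"]
        )
    df = records.copy()
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    df["days_in_month"] = df["date"].dt.days_in_month

    def _agg(g: pd.DataFrame) -> pd.Series:
        dim = g["days_in_month"].iloc[0]
        out = {}
        for col, name, how in (
            ("tmin", "mean_tmin", "mean"),
            ("tmax", "mean_tmax", "mean"),
            ("prcp", "total_prcp", "sum"),
        ):
            n_ok = g[col].notna().sum()
            if n_ok < 0.5 * dim:
                out[name] = np.nan
            elif how == "mean":
                out[name] = g[col].mean()
            else:
                out[name] = g[col].sum()
        return pd.Series(out)

    monthly = (
        df.groupby(["station_id", "year", "month"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return monthly


def fit_monthly_trends(
    monthly: pd.DataFrame,
    window_start: int = 1973,
    window_end: int = 2002,
    min_years: int = 3,
) -> pd.DataFrame:
    """Per-(station, month, variable) OLS of monthly aggregate vs calendar year.

    The abscissa is the calendar year itself (1973, 1974, ...).  Series with
    fewer than ``min_years`` non-missing years emit no trend (logged).
    Returns columns ``station_id, month, variable, slope, intercept, n_years``.
    """
    win = monthly[(monthly["year"] >= window_start) & (monthly["year"] <= window_end)]
    var_cols = {"tmin": "mean_tmin", "tmax": "mean_tmax", "prcp": "total_prcp"}
    rows = []
    for (sid, month), g in win.groupby(["station_id", "month"]):
        for var, col in var_cols.items():
            ok = g[col].notna()
            n = int(ok.sum())
            if n < min_years:
                logger.warning(
                    "station %s month %d %s: only %d year(s), no trend fitted", sid, month, var, n
                )
                continue
            slope, intercept = np.polyfit(g.loc[ok, "year"], g.loc[ok, col], 1)
            rows.append(
                {
                    "station_id": sid,
                    "month": int(month),
                    "variable": var,
                    "slope": slope,
                    "intercept": intercept,
                    "n_years": n,
                }
            )
    return pd.DataFrame(rows, columns=["station_id", "month", "variable", "slope", "intercept", "n_years"])


def calibration_means(
    monthly: pd.DataFrame, window_start: int = 1973, window_end: int = 2002
) -> pd.DataFrame:
    """Calibration-period mean of each monthly aggregate, per station and month."""
    win = monthly[(monthly["year"] >= window_start) & (monthly["year"] <= window_end)]
    return (
        win.groupby(["station_id", "month"])[["mean_tmin", "mean_tmax", "total_prcp"]]
        .mean()
        .reset_index()
    )


def scenario_at_year(
    trends: pd.DataFrame,
    calib_means: pd.DataFrame,
    target_year: int,
    station_id=None,
    label: str | None = None,
) -> ClimateScenario:
    """Build the trend scenario for a target year for one station.

    delta[m] = trend prediction at ``target_year`` minus the calibration-period
    mean of month m; precipitation becomes a multiplicative factor
    predicted/mean, floored at 0.
    """
    if station_id is not None:
        trends = trends[trends["station_id"] == station_id]
        calib_means = calib_means[calib_means["station_id"] == station_id]
    label = label or str(target_year)

    d_tmin, d_tmax, p_fac = np.zeros(12), np.zeros(12), np.ones(12)
    missing_months = []
    cm = calib_means.set_index("month")
    tr = trends.set_index(["month", "variable"])
    for m in MONTHS:
        have = all((m, v) in tr.index for v in ("tmin", "tmax")) and m in cm.index
        if not have:
            missing_months.append(int(m))
            continue
        for v, out in (("tmin", d_tmin), ("tmax", d_tmax)):
            row = tr.loc[(m, v)]
            pred = row["slope"] * target_year + row["intercept"]
            out[m - 1] = pred - cm.loc[m, f"mean_{v}"]
        if (m, "prcp") in tr.index:
            row = tr.loc[(m, "prcp")]
            pred = row["slope"] * target_year + row["intercept"]
            mean = cm.loc[m, "total_prcp"]
            if np.isfinite(mean) and mean > 0:
                p_fac[m - 1] = max(pred / mean, 0.0)
    if missing_months:
        raise ValueError(f"trends/means missing for month(s): {missing_months}")
    return ClimateScenario(label, d_tmin, d_tmax, p_fac, epoch="past")


ANOMALY_COLUMNS = ["label", "epoch", "ghg", "gcm", "month", "delta_tmin", "delta_tmax", "precip_factor"]


def load_anomaly_table(path) -> list[ClimateScenario]:
    """Read labelled 12-month anomaly groups from CSV; one scenario per label."""
    df = pd.read_csv(path, dtype={"label": str, "epoch": str, "ghg": str, "gcm": str})
    missing = [c for c in ANOMALY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anomaly table missing column(s): {missing}")
    scenarios = []
    for label, g in df.groupby("label", sort=False):
        months = sorted(g["month"].tolist())
        if months != list(range(1, 13)):
            raise ValueError(f"scenario {label!r}: need exactly months 1-12, got {months}")
        g = g.sort_values("month")
        scenarios.append(
            ClimateScenario(
                label=str(label),
                delta_tmin=g["delta_tmin"].to_numpy(),
                delta_tmax=g["delta_tmax"].to_numpy(),
                precip_factor=g["precip_factor"].to_numpy(),
                epoch=str(g["epoch"].iloc[0]),
                ghg=str(g["ghg"].iloc[0]),
                gcm=str(g["gcm"].iloc[0]),
            )
        )
    return scenarios


def write_anomaly_table(scenarios: list[ClimateScenario], path) -> None:
    rows = []
    for sc in scenarios:
        for m in MONTHS:
            rows.append(
                {
                    "label": sc.label,
                    "epoch": sc.epoch,
                    "ghg": sc.ghg,
                    "gcm": sc.gcm,
                    "month": int(m),
                    "delta_tmin": sc.delta_tmin[m - 1],
                    "delta_tmax": sc.delta_tmax[m - 1],
                    "precip_factor": sc.precip_factor[m - 1],
                }
            )
    pd.DataFrame(rows, columns=ANOMALY_COLUMNS).to_csv(path, index=False)
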