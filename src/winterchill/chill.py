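"""Chill accumulation models and the Safe Winter Chill statistic.

The Dynamic Model treats chill as a two-step chemical kinetic process: an
intermediate precursor accumulates reversibly at a temperature-dependent
rate (cold favours formation, warmth destroys it), and whenever the
intermediate pool reaches the threshold of one unit, a temperature-dependent
fraction of it is irreversibly banked as a Chill Portion (CP).  Per hour,
with TK the temperature in kelvin:

    ftmprt = slp * tetmlt * (TK - tetmlt) / TK
    xi     = e^ftmprt / (1 + e^ftmprt)            (conversion fraction)
    xs     = (a0/a1) * e^((e1-e0)/TK)             (equilibrium precursor level)
    ak1    = a1 * e^(-e1/TK)                      (first-order rate)
    S      = E_prev            if E_prev < 1
             E_prev*(1-xi_prev) otherwise          (pool after last conversion)
    E      = xs - (xs - S) * e^(-ak1)
    ΔCP    = xi * E  if E >= 1 else 0

Warm hours where the equilibrium xs < 1 can never complete a portion, which
is why the model saturates in hot climates and why frosts (very low rates
ak1) contribute almost nothing: the model's self-regulating window of
effective temperatures.

Chilling Hours (count of hours in (0, 7.2] °C) and the Utah Model (weighted
hours with negative weights above ~16 °C) are provided as comparators.

Safe Winter Chill (SWC) is the empirical 10% quantile of the distribution of
seasonal chill totals: the chill a grower can count on in 90% of winters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DynamicModelParams:
    """Kinetic constants of the Dynamic Model (canonical published values)."""

    slp: float = 1.6
    tetmlt: float = 277.0  # K
    e0: float = 4153.5  # K
    e1: float = 12888.8  # K
    a0: float = 1.395e5
    a1: float = 2.567e18

    def __post_init__(self):
        vals = [self.slp, self.tetmlt, self.e0, self.e1, self.a0, self.a1]
        if any(v <= 0 for v in vals):
            raise ValueError("all Dynamic Model constants must be positive")
        if self.e1 <= self.e0:
            raise ValueError("e1 must exceed e0")

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


DEFAULT_PARAMS = DynamicModelParams()


def _as_temps(hourly) -> np.ndarray:
    temps = np.asarray(hourly, dtype=float)
    bad = ~np.isfinite(temps)
    if bad.any():
        idx = np.where(bad)[0]
        where = idx[0]
        if isinstance(hourly, pd.Series):
            where = hourly.index[idx[0]]
        raise ValueError(f"non-finite temperature at {where} ({len(idx)} total)")
    return temps


def dynamic_chill(hourly, params: DynamicModelParams = DEFAULT_PARAMS, trace: bool = False):
    """Accumulated Chill Portions over an hourly temperature series.

    Returns the total CP, or ``(total, trace_frame)`` with per-hour
    intermediate level E and portion increments when ``trace=True``.
    """
    temps = _as_temps(hourly)
    if temps.size == 0:
        return (0.0, pd.DataFrame(columns=["E", "delta_cp"])) if trace else 0.0
    tk = temps + 273.0
    ftmprt = params.slp * params.tetmlt * (tk - params.tetmlt) / tk
    sr = np.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = (params.a0 / params.a1) * np.exp((params.e1 - params.e0) / tk)
    eak1 = np.exp(-params.a1 * np.exp(-params.e1 / tk))  # e^(-ak1)

    xi_l, xs_l, eak1_l = xi.tolist(), xs.tolist(), eak1.tolist()
    e = 0.0
    xi_prev = 0.0
    cp = 0.0
    e_trace = [] if trace else None
    d_trace = [] if trace else None
    for i in range(len(xi_l)):
        s = e if e < 1.0 else e * (1.0 - xi_prev)
        e = xs_l[i] - (xs_l[i] - s) * eak1_l[i]
        delt = xi_l[i] * e if e >= 1.0 else 0.0
        cp += delt
        xi_prev = xi_l[i]
        if trace:
            e_trace.append(e)
            d_trace.append(delt)
    if trace:
        tf = pd.DataFrame({"E": e_trace, "delta_cp": d_trace})
        if isinstance(hourly, pd.Series):
            tf.index = hourly.index
        return cp, tf
    return cp


def chilling_hours(hourly) -> float:
    """Hours with temperature in (0, 7.2] °C."""
    temps = _as_temps(hourly)
    return float(np.count_nonzero((temps > 0.0) & (temps <= 7.2)))


#: Utah Model weight bands, half-open (low, high] in °C
UTAH_BANDS = [
    (-np.inf, 1.4, 0.0),
    (1.4, 2.4, 0.5),
    (2.4, 9.1, 1.0),
    (9.1, 12.4, 0.5),
    (12.4, 15.9, 0.0),
    (15.9, 18.0, -0.5),
    (18.0, np.inf, -1.0),
]


def utah_chill(hourly) -> float:
    """Sum of Utah Model hourly weights (may be negative)."""
    temps = _as_temps(hourly)
    total = 0.0
    for low, high, w in UTAH_BANDS:
        if w != 0.0:
            total += w * np.count_nonzero((temps > low) & (temps <= high))
    return float(total)


MODELS = {
    "dynamic": dynamic_chill,
    "chilling_hours": chilling_hours,
    "utah": utah_chill,
}


def season_windows(index: pd.DatetimeIndex, latitude: float) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Complete dormancy-season windows covered by an hourly index.

    Northern hemisphere (lat >= 0): Oct 1 through Apr 30 23:00; southern:
    Apr 1 through Oct 31 23:00 (end dates half-open).  101 generated years
    hold 100 complete northern winters.
    """
    if len(index) == 0:
        return []
    first, last = index[0], index[-1]
    windows = []
    for year in range(first.year - 1, last.year + 1):
        if latitude >= 0:
            start = pd.Timestamp(year=year, month=10, day=1)
            end = pd.Timestamp(year=year + 1, month=5, day=1)
        else:
            start = pd.Timestamp(year=year, month=4, day=1)
            end = pd.Timestamp(year=year, month=11, day=1)
        if start >= first and end - pd.Timedelta(hours=1) <= last:
            windows.append((start, end))
    return windows


def season_chill(
    hourly: pd.Series,
    latitude: float,
    models=("dynamic", "chilling_hours", "utah"),
    params: DynamicModelParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Chill totals per dormancy season for the requested models.

    Returns columns ``season, model, value``; the season label is the year
    in which the window ends.
    """
    rows = []
    idx = hourly.index
    for start, end in season_windows(idx, latitude):
        i0, i1 = idx.searchsorted(start, side="left"), idx.searchsorted(end, side="left")
        chunk = hourly.iloc[i0:i1]
        label = end.year
        for model in models:
            if model == "dynamic":
                value = dynamic_chill(chunk, params)
            else:
                value = MODELS[model](chunk)
            rows.append({"season": label, "model": model, "value": value})
    return pd.DataFrame(rows, columns=["season", "model", "value"])


@dataclass
class SWCEstimate:
    swc: float
    n_winters: int
    station_id: str = ""
    scenario_label: str = ""
    model: str = "dynamic"


def safe_winter_chill(seasonal_totals, station_id="", scenario_label="", model="dynamic") -> SWCEstimate:
    """Empirical 10% quantile of seasonal chill totals.

    Linear interpolation between order statistics (position 0.1*(n-1)+1 on
    the sorted values); at least 10 seasons are required for the quantile to
    be meaningful.
    """
    totals = np.asarray(seasonal_totals, dtype=float)
    if totals.size < 10:
        raise ValueError(f"need >= 10 seasonal totals for a stable quantile, got {totals.size}")
    swc = float(np.quantile(totals, 0.1, method="linear"))
    return SWCEstimate(swc=swc, n_winters=int(totals.size),
                       station_id=station_id, scenario_label=scenario_label, model=model)
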