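"""Daily-to-hourly temperature reconstruction.

Chill models operate on hourly temperatures, but long station records carry
only daily minima and maxima.  The reconstruction uses the idealized diurnal
curve widely applied in dormancy modelling: between sunrise and sunset the
temperature follows a sine arc

    T(t) = Tmin + (Tmax - Tmin) * sin(pi * (t - sunrise) / (daylength + 4)),

and after sunset it declines logarithmically from the sunset temperature
T_ss towards the next day's minimum,

    T(tau) = T_ss - (T_ss - Tmin_next) * ln(tau) / ln(24 - daylength),

with tau the whole hours elapsed since sunset (anchored at tau = 1, since
ln 0 is undefined).  The decline reaches Tmin_next exactly at the next
sunrise.  Sunrise, sunset and daylength come from the solar declination
(7-term Fourier series in the day-angle) and the standard daylength
equation; everything is in local solar time, with no longitude correction —
chill totals are insensitive to a uniform phase shift of the diurnal cycle.

Days with daylength <= 4 h or >= 23 h fall back to a 24-point cosine
interpolation between Tmin and Tmax (the sine/log construction degenerates
near the poles); fallbacks are counted on the returned series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SolarDay:
    day_of_year: int
    latitude: float
    declination: float  # radians
    daylength: float  # hours, clamped to [0, 24]
    sunrise: float  # solar hours
    sunset: float


def declination(day_of_year) -> np.ndarray | float:
    """Solar declination (radians) from the 7-term Fourier series in the
    day angle Γ = 2π (J − 1) / 365."""
    g = 2.0 * np.pi * (np.asarray(day_of_year, dtype=float) - 1.0) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
    )


def _daylength_hours(latitude: float, decl) -> np.ndarray:
    phi = np.radians(latitude)
    cos_h = np.clip(-np.tan(phi) * np.tan(np.asarray(decl)), -1.0, 1.0)
    # hour angle at sunrise in degrees; 15° of hour angle per hour
    return (2.0 / 15.0) * np.degrees(np.arccos(cos_h))


def solar_day(latitude: float, day_of_year: int) -> SolarDay:
    """Declination, daylength and sunrise/sunset (solar time) for one day."""
    if abs(latitude) > 90:
        raise ValueError("latitude must lie in [-90, 90]")
    decl = float(declination(day_of_year))
    dl = float(_daylength_hours(latitude, decl))
    return SolarDay(
        day_of_year=day_of_year, latitude=latitude, declination=decl,
        daylength=dl, sunrise=12.0 - dl / 2.0, sunset=12.0 + dl / 2.0,
    )


def night_temp(t_sunset, tmin_next, daylength, tau):
    """Logarithmic night decline, anchored at one hour after sunset."""
    tau = np.maximum(tau, 1.0)
    return t_sunset - (t_sunset - tmin_next) * np.log(tau) / np.log(24.0 - daylength)


def hourly_from_daily(days: pd.DataFrame, latitude: float) -> pd.Series:
    """Reconstruct hourly temperatures from a daily (date, tmin, tmax) frame.

    Returns a Series indexed by hourly timestamps (24 per day, hours 0-23)
    with ``attrs['n_fallback_days']`` counting polar fallback days.  Needs at
    least two consecutive days; the last night reuses the final day's own
    minimum (there is no later day to take it from).
    """
    if len(days) < 2:
        raise ValueError("need >= 2 consecutive days (the night reaches into the next day)")
    days = days.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(days["date"])
    tmin = days["tmin"].to_numpy(dtype=float)
    tmax = days["tmax"].to_numpy(dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in input days")

    doy = dates.dayofyear.to_numpy()
    decl = declination(doy)
    dl = _daylength_hours(latitude, decl)
    rise = 12.0 - dl / 2.0
    sset = 12.0 + dl / 2.0
    fallback = (dl <= 4.0) | (dl >= 23.0)
    n_fallback = int(fallback.sum())
    if n_fallback:
        logger.warning("%d day(s) fell back to cosine interpolation (polar daylength)", n_fallback)

    # sine value at sunset (the start of the night decline)
    t_ss = tmin + (tmax - tmin) * np.sin(np.pi * dl / (dl + 4.0))

    nd = len(days)
    H = np.tile(np.arange(24.0), (nd, 1))  # (day, hour-of-day)
    tmin_next = np.roll(tmin, -1)
    tmin_next[-1] = tmin[-1]

    col = lambda a: a[:, None]
    day_mask = (H >= col(rise)) & (H <= col(sset))
    with np.errstate(invalid="ignore", divide="ignore"):
        T_day = col(tmin) + col(tmax - tmin) * np.sin(np.pi * (H - col(rise)) / col(dl + 4.0))
        # after this day's sunset, towards next day's tmin
        T_even = night_temp(col(t_ss), col(tmin_next), col(dl), H - col(sset))
        # before this day's sunrise: still on the previous day's decline
        prev = lambda a: np.roll(a, 1)
        T_morn = night_temp(
            col(prev(t_ss)), col(tmin), col(prev(dl)), H + 24.0 - col(prev(sset))
        )
    T = np.where(day_mask, T_day, np.where(H > col(sset), T_even, T_morn))

    # first day has no previous sunset: backfill pre-sunrise hours with its tmin
    T[0, H[0] < rise[0]] = tmin[0]
    # a day following a polar-fallback day has no valid previous decline
    after_fb = np.zeros(nd, dtype=bool)
    after_fb[1:] = fallback[:-1]
    for d in np.where(after_fb & ~fallback)[0]:
        T[d, H[d] < rise[d]] = tmin[d]
    # polar fallback: cosine interpolation over the day's 24 hours
    if n_fallback:
        hh = np.arange(24.0)
        for d in np.where(fallback)[0]:
            T[d] = tmin[d] + (tmax[d] - tmin[d]) * (1.0 - np.cos(2.0 * np.pi * hh / 24.0)) / 2.0

    index = dates.repeat(24) + pd.to_timedelta(np.tile(np.arange(24), nd), unit="h")
    out = pd.Series(T.ravel(), index=index, name="temp_C")
    out.attrs["n_fallback_days"] = n_fallback
    return out


def write_hourly_csv(series: pd.Series, station_id: str, path) -> None:
    frame = pd.DataFrame(
        {"station_id": station_id, "timestamp": series.index, "temp_C": series.to_numpy()}
    )
    frame.to_csv(path, index=False)
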