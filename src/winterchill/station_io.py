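"""Reading, validating and quality-filtering daily station weather records.

Daily records are kept as a pandas DataFrame with columns
``station_id, date, tmin, tmax, prcp`` (temperatures in °C, precipitation in
mm, missing values as NaN); station metadata as a DataFrame with
``station_id, lat, lon, elev``.  The quality filter reproduces the standard
archive screening for multi-decade chill studies: a station survives a
calibration window when it has at least 5000 daily records in the window and
no more than 25% of its daily minimum or maximum temperatures, nor more than
50% of its rainfall values, missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["station_id", "date", "tmin", "tmax", "prcp"]
META_COLUMNS = ["station_id", "lat", "lon", "elev"]

#: archive screening thresholds (calibration window 1973-2002 by default)
MIN_RECORDS = 5000
MAX_MISSING_TEMP = 0.25
MAX_MISSING_PRCP = 0.50

_NA_VALUES = ["", "NA"]


def read_station_metadata(path) -> pd.DataFrame:
    """Read the station metadata CSV (``station_id,lat,lon,elev``).

    Latitude/longitude are validated against their geographic bounds and
    station ids must be unique.
    """
    meta = pd.read_csv(path, na_values=_NA_VALUES, dtype={"station_id": str})
    missing = [c for c in META_COLUMNS[:3] if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file is missing required column(s): {missing}")
    if "elev" not in meta.columns:
        meta["elev"] = np.nan
    dupes = meta.loc[meta["station_id"].duplicated(), "station_id"].tolist()
    if dupes:
        raise ValueError(f"duplicate station ids in metadata: {sorted(set(dupes))}")
    bad_lat = meta.loc[(meta["lat"] < -90) | (meta["lat"] > 90), "station_id"].tolist()
    bad_lon = meta.loc[(meta["lon"] < -180) | (meta["lon"] > 180), "station_id"].tolist()
    if bad_lat or bad_lon:
        raise ValueError(
            f"coordinates out of bounds: lat {bad_lat}, lon {bad_lon}"
        )
    return meta[META_COLUMNS]


def read_daily_records(path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read daily records plus metadata; return ``(metadata, records)``.

    Unparseable numeric cells become missing.  Rows with tmax < tmin are
    retained with both temperatures set missing (and counted in the log);
    negative precipitation becomes missing.  A station appearing in the data
    but not in the metadata is a hard error.
    """
    meta = read_station_metadata(metadata_path)
    raw = pd.read_csv(path, na_values=_NA_VALUES, dtype={"station_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"daily records file is missing required column(s): {missing}")
    rec = raw[RECORD_COLUMNS].copy()
    rec["date"] = pd.to_datetime(rec["date"], format="ISO8601", errors="raise")
    for col in ("tmin", "tmax", "prcp"):
        rec[col] = pd.to_numeric(rec[col], errors="coerce")

    inverted = rec["tmin"].notna() & rec["tmax"].notna() & (rec["tmax"] < rec["tmin"])
    if inverted.any():
        logger.warning("%d record(s) with tmax < tmin; temperatures set missing", inverted.sum())
        rec.loc[inverted, ["tmin", "tmax"]] = np.nan
    neg_prcp = rec["prcp"].notna() & (rec["prcp"] < 0)
    if neg_prcp.any():
        logger.warning("%d record(s) with negative precipitation set missing", neg_prcp.sum())
        rec.loc[neg_prcp, "prcp"] = np.nan

    unknown = sorted(set(rec["station_id"]) - set(meta["station_id"]))
    if unknown:
        raise ValueError(f"stations present in data but absent from metadata: {unknown}")

    dup = rec.duplicated(subset=["station_id", "date"])
    if dup.any():
        logger.warning("%d duplicate station-day row(s) dropped (first kept)", dup.sum())
        rec = rec[~dup].reset_index(drop=True)
    return meta, rec


def quality_filter(
    records: pd.DataFrame,
    window_start: int = 1973,
    window_end: int = 2002,
    station_ids=None,
) -> pd.DataFrame:
    """Screen stations over a calibration window of calendar years.

    Returns one row per station: ``station_id, n_days, frac_missing_tmin,
    frac_missing_tmax, frac_missing_prcp, passed``.  ``n_days`` counts rows
    present in the window with at least one variable non-missing; the
    missingness fractions are ratios over those days.  Thresholds are
    inclusive on the passing side (exactly 25% missing still passes).
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    years = records["date"].dt.year
    win = records[(years >= window_start) & (years <= window_end)]
    any_present = win[["tmin", "tmax", "prcp"]].notna().any(axis=1)
    win = win[any_present]

    ids = sorted(set(records["station_id"]) if station_ids is None else set(station_ids))
    grouped = win.groupby("station_id")
    rows = []
    for sid in ids:
        if sid in grouped.groups:
            g = grouped.get_group(sid)
            n = len(g)
            fr = {c: float(g[c].isna().mean()) for c in ("tmin", "tmax", "prcp")}
        else:
            n, fr = 0, {"tmin": 1.0, "tmax": 1.0, "prcp": 1.0}
        passed = (
            n >= MIN_RECORDS
            and fr["tmin"] <= MAX_MISSING_TEMP
            and fr["tmax"] <= MAX_MISSING_TEMP
            and fr["prcp"] <= MAX_MISSING_PRCP
        )
        rows.append(
            {
                "station_id": sid,
                "n_days": n,
                "frac_missing_tmin": fr["tmin"],
                "frac_missing_tmax": fr["tmax"],
                "frac_missing_prcp": fr["prcp"],
                "passed": passed,
            }
        )
    return pd.DataFrame(rows, columns=[
        "station_id", "n_days", "frac_missing_tmin", "frac_missing_tmax",
        "frac_missing_prcp", "passed",
    ])


def write_daily_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="NA")


def write_quality_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)
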