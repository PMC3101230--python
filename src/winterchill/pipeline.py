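"""End-to-end orchestration: records → scenarios → weather → chill → maps.

``run_pipeline`` executes the full analysis for every surviving station and
every requested climate scenario: quality filtering, monthly trend
regressions, baseline (typical-year) and anomaly-table scenarios, 101-year
synthetic weather generation, hourly reconstruction, seasonal chill
accumulation with the selected models, Safe Winter Chill, and — when enough
stations survive — kriged, temperature-corrected, masked chill surfaces.
Everything is deterministic given the config and its seed; the run manifest
records per-stage counts, warnings and SHA-256 checksums of every output.

``make_fixtures`` fabricates a self-contained toy world (12 stations across
a 40 °C mean-annual-temperature gradient, 18 future scenario labels spanning
2 epochs × 3 emissions pathways × 3 climate models, and a fine-scale
temperature raster) that loads through the same file interfaces as real
archive data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import chill, hourly, scenarios, spatial, station_io, synthetic_weather

logger = logging.getLogger(__name__)

ALL_MODELS = ("dynamic", "chilling_hours", "utah")


@dataclass
class RunConfig:
    stations_path: str
    metadata_path: str
    out_dir: str
    anomalies_path: str | None = None
    scenario_labels: list[str] | None = None  # None = all available
    past_years: tuple[int, int] = (1975, 2000)
    window: tuple[int, int] = (1973, 2002)
    n_years: int = 101
    models: tuple[str, ...] = ALL_MODELS
    seed: int = 1
    grid: dict | None = None  # lon_min, lon_max, lat_min, lat_max, res
    t_highres_path: str | None = None
    max_dist_deg: float = spatial.DIST_MASK_DEG
    temp_mask_range: tuple[float, float] = spatial.TEMP_MASK_RANGE
    skip_quality_filter: bool = False

    def __post_init__(self):
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown chill model(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("past_years", "window", "models", "temp_mask_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.stations_path, self.metadata_path, self.anomalies_path, self.t_highres_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _station_seed(base_seed: int, station_idx: int, scen_idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, station_idx, scen_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "warnings": {}}

    # --- filter -----------------------------------------------------------
    meta, records = station_io.read_daily_records(config.stations_path, config.metadata_path)
    report = station_io.quality_filter(records, *config.window)
    station_io.write_quality_report(report, out / "quality_report.csv")
    if config.skip_quality_filter:
        keep = list(report["station_id"])
    else:
        keep = list(report.loc[report["passed"], "station_id"])
    if not keep:
        raise RuntimeError("stage filter: no station passed the quality filter")
    meta = meta[meta["station_id"].isin(keep)].reset_index(drop=True)
    records = records[records["station_id"].isin(keep)]
    manifest["stages"]["filter"] = {"n_stations_in": len(report), "n_stations_passed": len(keep)}

    # --- scenarios --------------------------------------------------------
    monthly = scenarios.monthly_aggregate(records)
    trends = scenarios.fit_monthly_trends(monthly, *config.window)
    calib = scenarios.calibration_means(monthly, *config.window)
    anomaly_scens = scenarios.load_anomaly_table(config.anomalies_path) if config.anomalies_path else []
    if config.scenario_labels is not None:
        anomaly_scens = [s for s in anomaly_scens if s.label in config.scenario_labels]
    manifest["stages"]["scenarios"] = {
        "past_years": list(config.past_years),
        "n_anomaly_scenarios": len(anomaly_scens),
    }

    # --- per station × scenario chill -------------------------------------
    seasonal_rows, swc_rows, tmean_rows = [], [], []
    n_clamped = 0
    n_fallback = 0
    for si, st in meta.iterrows():
        sid = st["station_id"]
        st_rec = records[records["station_id"] == sid]
        try:
            params = synthetic_weather.calibrate(st_rec)
        except ValueError as exc:
            raise RuntimeError(f"stage calibrate: station {sid}: {exc}") from exc
        past = [
            scenarios.scenario_at_year(trends, calib, y, station_id=sid, label=str(y))
            for y in config.past_years
        ]
        scens = past + anomaly_scens
        if config.scenario_labels is not None:
            scens = [s for s in scens if s.label in config.scenario_labels]
        for ci, scen in enumerate(scens):
            seed = _station_seed(config.seed, int(si), ci)
            try:
                series = synthetic_weather.generate(
                    params, scen, n_years=config.n_years, seed=seed, station_id=sid
                )
                hseries = hourly.hourly_from_daily(series.days, st["lat"])
                seasons = chill.season_chill(hseries, st["lat"], models=config.models)
            except Exception as exc:
                raise RuntimeError(f"stage chill: station {sid}, scenario {scen.label}: {exc}") from exc
            n_clamped += series.n_clamped
            n_fallback += hseries.attrs.get("n_fallback_days", 0)
            tmean_rows.append({
                "station_id": sid, "scenario": scen.label,
                "t_mean": float((series.days["tmin"] + series.days["tmax"]).mean() / 2.0),
            })
            for _, row in seasons.iterrows():
                seasonal_rows.append({
                    "station_id": sid, "scenario": scen.label,
                    "season": int(row["season"]), "model": row["model"], "value": row["value"],
                })
            for model in config.models:
                totals = seasons.loc[seasons["model"] == model, "value"]
                est = chill.safe_winter_chill(totals, sid, scen.label, model)
                swc_rows.append({
                    "station_id": sid, "scenario": scen.label, "model": model,
                    "swc": est.swc, "n_winters": est.n_winters,
                })
    seasonal = pd.DataFrame(seasonal_rows)
    swc = pd.DataFrame(swc_rows)
    tmeans = pd.DataFrame(tmean_rows)
    seasonal.to_csv(out / "seasonal_chill.csv", index=False)
    swc.to_csv(out / "swc.csv", index=False)
    tmeans.to_csv(out / "station_tmean.csv", index=False)
    manifest["stages"]["chill"] = {
        "n_stations": len(meta),
        "n_scenarios": int(swc.groupby("station_id")["scenario"].nunique().max()) if len(swc) else 0,
        "n_swc_rows": len(swc),
    }
    manifest["warnings"]["tmax_clamped_days"] = int(n_clamped)
    manifest["warnings"]["hourly_fallback_days"] = int(n_fallback)

    # --- spatial ----------------------------------------------------------
    wants_spatial = config.grid is not None or config.t_highres_path is not None
    if wants_spatial and len(meta) >= 13:
        t_highres = None
        if config.t_highres_path:
            # the fine raster defines the grid so the layers stay co-registered
            lons, lats, t_highres = spatial.read_temperature_raster(config.t_highres_path)
        else:
            g = config.grid
            lons, lats = spatial.make_grid(
                g["lon_min"], g["lon_max"], g["lat_min"], g["lat_max"], g.get("res", 0.1)
            )
        surfaces = {}
        for scen_label, group in swc[swc["model"] == "dynamic"].groupby("scenario"):
            pts = group.merge(meta, on="station_id").merge(
                tmeans[tmeans["scenario"] == scen_label], on="station_id"
            )
            pts = pts.rename(columns={"lat": "lat", "lon": "lon"})
            surf, diag = spatial.build_surface(pts, lons, lats, t_highres)
            if t_highres is not None:
                try:
                    cp = spatial.fit_cp_polynomial(pts["t_mean"], pts["swc"])
                    surf = spatial.correct_surface(surf, cp)
                except ValueError as exc:  # too few stations / narrow T span
                    logger.warning("scenario %s: correction skipped (%s)", scen_label, exc)
                    diag["correction_skipped"] = str(exc)
            surf = spatial.mask_surface(surf, pts, config.max_dist_deg, config.temp_mask_range)
            path = out / f"surface_{scen_label}.nc"
            surf.to_netcdf(path)
            surfaces[scen_label] = diag
        manifest["stages"]["spatial"] = {"n_surfaces": len(surfaces), "diagnostics": surfaces}
    else:
        manifest["stages"]["spatial"] = {
            "skipped": True,
            "reason": "no grid or fine raster configured" if not wants_spatial
            else f"only {len(meta)} stations (kriging needs >= 13)",
        }

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# toy-world fixture bundle

_GHG_WARMING = {"B1": 1.0, "A1B": 1.4, "A2": 1.7}  # relative pathway strength
_GCM_FACTOR = {"CSIRO": 0.85, "HADCM3": 1.0, "MIROC": 1.25}
_EPOCH_WARMING = {"mid": 1.2, "end": 2.0}  # °C base warming per epoch


def make_future_scenarios(seed: int = 0) -> list[scenarios.ClimateScenario]:
    """The 18 future scenario labels: 2 epochs × 3 pathways × 3 models.

    Warming scales with epoch, pathway and model (matching the ordering
    MIROC > HADCM3 > CSIRO and A2 > A1B > B1), is slightly stronger in
    winter months, and carries small reproducible monthly jitter.
    """
    rng = np.random.default_rng(seed)
    out = []
    m = np.arange(12)
    winter_weight = 1.0 + 0.25 * np.cos(2 * np.pi * m / 12.0)  # more warming in NH winter
    for epoch, base in _EPOCH_WARMING.items():
        for ghg, gw in _GHG_WARMING.items():
            for gcm, cf in _GCM_FACTOR.items():
                warm = base * gw * cf * winter_weight + rng.normal(0, 0.1, 12)
                out.append(scenarios.ClimateScenario(
                    label=f"{epoch}_{ghg}_{gcm}",
                    delta_tmin=warm * 1.1,  # minima warm slightly faster
                    delta_tmax=warm * 0.9,
                    precip_factor=np.clip(1.0 + rng.normal(0, 0.08, 12), 0.5, 1.5),
                    epoch=epoch, ghg=ghg, gcm=gcm,
                ))
    return out


def make_fixtures(seed: int, out_dir, n_stations: int = 12, n_years: int = 30,
                  raster_res: float = 0.25, lat_range: tuple[float, float] = (8.0, 64.0)) -> dict:
    """Write a self-contained toy world to ``out_dir``.

    Stations span ~40 °C of mean annual temperature from the subtropics to
    the subarctic; "observed" records are generated from fabricated site
    parameters with a mild warming trend folded in, so the monthly trend
    regressions have signal to find.  Returns the bundle's file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_stations + 1)]

    lat = np.linspace(lat_range[0], lat_range[1], n_stations)
    mat = 28.0 - 40.0 * (lat - 8.0) / 56.0  # ~40 °C gradient from lat 8 to 64
    lon = 10.0 + rng.uniform(-4.0, 4.0, n_stations)
    meta_rows, rec_frames = [], []
    for i in range(n_stations):
        sid = f"SYN{i:03d}"
        meta_rows.append({"station_id": sid, "lat": round(lat[i], 3),
                          "lon": round(lon[i], 3), "elev": round(float(rng.uniform(10, 800)), 0)})
        params = synthetic_weather.synthetic_site_params(lat[i], mat[i], seed=child_seeds[i])
        series = synthetic_weather.generate(
            params, None, n_years=n_years, seed=child_seeds[i],
            station_id=sid, start_year=1973,
        )
        days = series.days.copy()
        trend = 0.03 * (days["date"].dt.year - 1973)  # °C/yr warming signal
        days["tmin"] += trend
        days["tmax"] += trend
        days.insert(0, "station_id", sid)
        rec_frames.append(days)
    records = pd.concat(rec_frames, ignore_index=True)
    for col in ("tmin", "tmax", "prcp"):
        records[col] = records[col].round(2)

    paths = {
        "metadata": out / "stations_meta.csv",
        "records": out / "stations_daily.csv",
        "anomalies": out / "anomalies.csv",
        "t_highres": out / "t_highres.nc",
    }
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)
    station_io.write_daily_records(records, paths["records"])
    scenarios.write_anomaly_table(make_future_scenarios(child_seeds[-1]), paths["anomalies"])

    # fine-scale temperature raster: latitudinal gradient + terrain-like noise
    lon_min, lon_max = lon.min() - 3, lon.max() + 3
    lat_min, lat_max = lat.min() - 3, lat.max() + 3
    lons, lats = spatial.make_grid(lon_min, lon_max, lat_min, lat_max, raster_res)
    glon, glat = np.meshgrid(lons, lats)
    mat_of_lat = 28.0 - 40.0 * (glat - 8.0) / 56.0
    terrain = 1.5 * np.sin(glon * 0.9) * np.cos(glat * 0.7) + rng.normal(0, 0.5, glon.shape)
    t_grid = mat_of_lat + terrain
    ds = xr.Dataset({"t_mean_annual": (("lat", "lon"), t_grid)},
                    coords={"lat": lats, "lon": lons})
    ds.to_netcdf(paths["t_highres"], engine="scipy")
    return {k: str(v) for k, v in paths.items()}
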