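"""Spatial interpolation and temperature correction of Safe Winter Chill.

Station SWC estimates are interpolated to a regular lat/lon grid (0.1° by
default) by ordinary kriging restricted to the 12 nearest stations, with a
spherical semivariogram fitted by least squares to the binned empirical
semivariogram.  Because stations are sparse, the raw interpolation misses
fine-scale temperature structure; a degree-5 polynomial CP(T) fitted between
station mean annual temperature and station SWC supplies a correction:

    SWC_corr = SWC_int + CP(T_interp + T_diff) - CP(T_interp)

where T_interp is the kriged station-temperature surface and
T_diff = T_highres - T_interp the temperature variation a high-resolution
climatology resolves but the station interpolation does not.  CP(T) is
evaluated as max(polynomial, 0) inside its fitted validity range and 0
outside.  Cells further than 5° (plane Euclidean distance in degrees) from
the nearest station, or with high-resolution mean annual temperature below
0 °C or above 20 °C, are masked as unreliable/unsuitable.

Rasters are exchanged as xarray Datasets (NetCDF) or plain CSV grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DIST_MASK_DEG = 5.0
TEMP_MASK_RANGE = (0.0, 20.0)


def make_grid(lon_min, lon_max, lat_min, lat_max, res: float = 0.1):
    """Cell-centre coordinate vectors of a regular lon/lat grid."""
    lons = np.arange(lon_min + res / 2.0, lon_max, res)
    lats = np.arange(lat_min + res / 2.0, lat_max, res)
    return lons, lats


def spherical(h, nugget, psill, rng):
    """Spherical semivariogram model."""
    h = np.asarray(h, dtype=float)
    hr = np.minimum(h / max(rng, 1e-12), 1.0)
    gamma = nugget + psill * (1.5 * hr - 0.5 * hr**3)
    return np.where(h == 0.0, 0.0, gamma)


def fit_spherical_variogram(coords: np.ndarray, values: np.ndarray,
                            n_bins: int = 15, cutoff_frac: float = 0.4):
    """Fit (nugget, partial sill, range) to the binned empirical semivariogram.

    Pairwise semivariances are binned into ``n_bins`` equal-width distance
    bins up to ``cutoff_frac`` of the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    gam = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    cutoff = cutoff_frac * dist.max()
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist > lo) & (dist <= hi)
        if sel.any():
            centers.append(dist[sel].mean())
            means.append(gam[sel].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    if len(centers) < 3 or means.max() < 1e-15:
        # flat or near-degenerate field: pure nugget-free linear-ish model
        return 0.0, float(max(means.max(), 1e-12)) if len(means) else 1e-12, float(max(cutoff, 1e-6))

    def resid(p):
        return spherical(centers, *p) - means

    p0 = np.array([0.0, means.max(), max(centers.max(), 1e-6)])
    sol = least_squares(resid, p0, bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]))
    nugget, psill, rng = sol.x
    return float(nugget), float(psill), float(rng)


def krige(points: pd.DataFrame, lons: np.ndarray, lats: np.ndarray,
          n_neighbors: int = 12, value_col: str = "value",
          variogram: tuple | None = None):
    """12-neighbor ordinary kriging of station point values onto a grid.

    ``points`` needs columns ``lon, lat`` and ``value_col``; duplicate
    coordinates are rejected.  Returns ``(grid, diagnostics)`` where grid has
    shape (len(lats), len(lons)).  A grid cell coinciding with a station
    returns that station's value exactly; singular kriging systems fall back
    to inverse-distance weighting (counted in diagnostics).  Kriging weights
    always sum to 1; the worst deviation across cells is reported.
    """
    coords = points[["lon", "lat"]].to_numpy(dtype=float)
    values = points[value_col].to_numpy(dtype=float)
    n = len(values)
    if n < n_neighbors + 1:
        raise ValueError(f"kriging needs >= {n_neighbors + 1} stations, got {n}")
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("duplicate station coordinates")

    if variogram is None:
        variogram = fit_spherical_variogram(coords, values)
    nugget, psill, vrange = variogram

    tree = cKDTree(coords)
    glon, glat = np.meshgrid(lons, lats)
    cells = np.column_stack([glon.ravel(), glat.ravel()])
    dists, idxs = tree.query(cells, k=n_neighbors)

    out = np.empty(len(cells))
    n_idw = 0
    max_weight_dev = 0.0
    k = n_neighbors
    ones = np.ones(k)
    for c in range(len(cells)):
        d0 = dists[c]
        nb = idxs[c]
        if d0[0] < 1e-9:  # exact interpolator at station locations
            out[c] = values[nb[0]]
            continue
        sub = coords[nb]
        dmat = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = spherical(dmat, nugget, psill, vrange)
        A[k, :k] = 1.0
        A[:k, k] = 1.0
        A[k, k] = 0.0
        b = np.empty(k + 1)
        b[:k] = spherical(d0, nugget, psill, vrange)
        b[k] = 1.0
        try:
            sol = np.linalg.solve(A, b)
            w = sol[:k]
            dev = abs(w.sum() - 1.0)
            if not np.isfinite(dev) or dev > 1e-6:
                raise np.linalg.LinAlgError("weights do not sum to 1")
            max_weight_dev = max(max_weight_dev, dev)
            out[c] = w @ values[nb]
        except np.linalg.LinAlgError:
            n_idw += 1
            iw = 1.0 / np.maximum(d0, 1e-12) ** 2
            out[c] = (iw @ values[nb]) / iw.sum()
    if n_idw:
        logger.warning("%d cell(s) fell back to inverse-distance weighting", n_idw)
    diagnostics = {
        "variogram": {"nugget": nugget, "psill": psill, "range": vrange},
        "n_idw_fallback": n_idw,
        "max_weight_sum_deviation": max_weight_dev,
    }
    return out.reshape(len(lats), len(lons)), diagnostics


@dataclass
class PolynomialCorrection:
    """Degree-5 CP(T) relation with a validity range outside which CP = 0."""

    poly: np.polynomial.Polynomial
    valid_range: tuple[float, float]

    def __call__(self, temps):
        temps = np.asarray(temps, dtype=float)
        lo, hi = self.valid_range
        inside = (temps > lo) & (temps < hi)
        vals = np.where(inside, np.maximum(self.poly(temps), 0.0), 0.0)
        return vals if vals.ndim else float(vals)


def fit_cp_polynomial(mean_annual_temp, swc, min_stations: int = 20,
                      min_span: float = 10.0) -> PolynomialCorrection:
    """Degree-5 least-squares fit of SWC against mean annual temperature.

    The design is centred/scaled internally.  The validity range is the
    widest contiguous interval containing the bulk of the data on which the
    fitted polynomial is non-negative.
    """
    t = np.asarray(mean_annual_temp, dtype=float)
    y = np.asarray(swc, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < min_stations:
        raise ValueError(f"need >= {min_stations} stations, got {len(t)}")
    span = t.max() - t.min()
    if span < min_span:
        raise ValueError(
            f"temperature span {span:.1f} °C too narrow (< {min_span} °C); "
            "the degree-5 design is ill-conditioned even after internal centering/scaling"
        )
    poly = np.polynomial.Polynomial.fit(t, y, deg=5).convert()

    # widest contiguous non-negative interval containing the data median
    grid = np.linspace(t.min() - 10.0, t.max() + 10.0, 4001)
    nonneg = poly(grid) >= 0.0
    med = float(np.median(t))
    i_med = int(np.searchsorted(grid, med))
    if not nonneg[min(i_med, len(grid) - 1)]:
        # fall back to the longest non-negative run overlapping the data span
        best = (0, 0)
        i = 0
        while i < len(grid):
            if nonneg[i]:
                j = i
                while j < len(grid) and nonneg[j]:
                    j += 1
                if j - i > best[1] - best[0]:
                    best = (i, j)
                i = j
            else:
                i += 1
        lo_i, hi_i = best
    else:
        lo_i = i_med
        while lo_i > 0 and nonneg[lo_i - 1]:
            lo_i -= 1
        hi_i = i_med
        while hi_i < len(grid) - 1 and nonneg[hi_i + 1]:
            hi_i += 1
        hi_i += 1
    return PolynomialCorrection(poly=poly, valid_range=(float(grid[lo_i]), float(grid[min(hi_i, len(grid) - 1)])))


@dataclass
class ChillSurface:
    """Gridded SWC with its temperature surfaces and reliability masks."""

    lons: np.ndarray
    lats: np.ndarray
    swc_int: np.ndarray
    t_interp: np.ndarray
    t_highres: np.ndarray | None = None
    t_diff: np.ndarray | None = None
    swc_corr: np.ndarray | None = None
    mask_distance: np.ndarray | None = None
    mask_temperature: np.ndarray | None = None

    def __post_init__(self):
        shape = (len(self.lats), len(self.lons))
        for name in ("swc_int", "t_interp", "t_highres", "t_diff",
                     "swc_corr", "mask_distance", "mask_temperature"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")

    @property
    def combined_mask(self) -> np.ndarray:
        m = np.zeros((len(self.lats), len(self.lons)), dtype=bool)
        if self.mask_distance is not None:
            m |= self.mask_distance
        if self.mask_temperature is not None:
            m |= self.mask_temperature
        return m

    def to_dataset(self) -> xr.Dataset:
        data = {}
        for name in ("swc_int", "t_interp", "t_highres", "t_diff", "swc_corr"):
            arr = getattr(self, name)
            if arr is not None:
                data[name] = (("lat", "lon"), arr.astype(float))
        for name in ("mask_distance", "mask_temperature"):
            arr = getattr(self, name)
            if arr is not None:
                data[name] = (("lat", "lon"), arr.astype(np.int8))
        if self.swc_corr is not None and (self.mask_distance is not None or self.mask_temperature is not None):
            export = self.swc_corr.astype(float).copy()
            export[self.combined_mask] = np.nan
            data["swc_masked"] = (("lat", "lon"), export)
        return xr.Dataset(data, coords={"lat": self.lats, "lon": self.lons})

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def build_surface(stations: pd.DataFrame, lons, lats, t_highres: np.ndarray | None = None,
                  n_neighbors: int = 12) -> tuple[ChillSurface, dict]:
    """Krige station SWC and mean annual temperature onto the grid.

    ``stations`` needs columns ``lon, lat, swc, t_mean``.  When a co-registered
    high-resolution temperature raster is supplied, ``t_diff`` is computed.
    """
    swc_int, diag_swc = krige(stations, lons, lats, n_neighbors, value_col="swc")
    t_interp, diag_t = krige(stations, lons, lats, n_neighbors, value_col="t_mean")
    t_diff = t_highres - t_interp if t_highres is not None else None
    surf = ChillSurface(lons=np.asarray(lons), lats=np.asarray(lats),
                        swc_int=swc_int, t_interp=t_interp,
                        t_highres=t_highres, t_diff=t_diff)
    return surf, {"swc": diag_swc, "t_mean": diag_t}


def correct_surface(surface: ChillSurface, cp: PolynomialCorrection) -> ChillSurface:
    """Apply the polynomial temperature correction; result floored at 0."""
    if surface.t_diff is None:
        raise ValueError("surface has no t_diff (supply a high-resolution temperature raster)")
    corrected = surface.swc_int + cp(surface.t_interp + surface.t_diff) - cp(surface.t_interp)
    surface.swc_corr = np.maximum(corrected, 0.0)
    return surface


def mask_surface(surface: ChillSurface, stations: pd.DataFrame,
                 max_dist_deg: float = DIST_MASK_DEG,
                 temp_range: tuple[float, float] = TEMP_MASK_RANGE) -> ChillSurface:
    """Flag cells far from any station or outside the suitable temperature band."""
    coords = stations[["lon", "lat"]].to_numpy(dtype=float)
    tree = cKDTree(coords)
    glon, glat = np.meshgrid(surface.lons, surface.lats)
    d, _ = tree.query(np.column_stack([glon.ravel(), glat.ravel()]), k=1)
    surface.mask_distance = (d > max_dist_deg).reshape(glon.shape)
    if surface.t_highres is not None:
        lo, hi = temp_range
        surface.mask_temperature = (surface.t_highres < lo) | (surface.t_highres > hi)
    else:
        surface.mask_temperature = np.zeros(glon.shape, dtype=bool)
    return surface


def read_temperature_raster(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a mean-annual-temperature raster (NetCDF with lat/lon dims).

    Returns ``(lons, lats, values)`` with values shaped (lat, lon).
    """
    ds = xr.open_dataset(path, engine="scipy")
    var = [v for v in ds.data_vars][0]
    arr = ds[var]
    return ds["lon"].to_numpy(), ds["lat"].to_numpy(), arr.to_numpy()
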