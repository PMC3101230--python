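"""Kriging, polynomial temperature correction and reliability masks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from winterchill import spatial


def _smooth_world(rng, n_stations=50, noise=1.0):
    """A synthetic region where true SWC is a smooth function of a fine
    temperature field (latitudinal gradient + terrain-like structure)."""
    lons, lats = spatial.make_grid(0.0, 5.0, 40.0, 50.0, 0.1)
    glon, glat = np.meshgrid(lons, lats)
    t_true = (
        24.0 - 1.8 * (glat - 40.0)
        + 1.5 * np.sin(glon * 1.2) * np.cos(glat * 0.8)
        + rng.normal(0.0, noise, glon.shape)
    )
    g = lambda T: 100.0 * np.exp(-(((T - 8.0) / 9.0) ** 2))
    idx = rng.choice(glon.size, n_stations, replace=False)
    stations = pd.DataFrame(
        {"lon": glon.ravel()[idx], "lat": glat.ravel()[idx], "t_mean": t_true.ravel()[idx]}
    )
    stations["swc"] = g(stations["t_mean"])
    return lons, lats, glon, glat, t_true, g, stations


class TestKriging:
    def test_exact_at_station_cells(self, rng):
        lons, lats, glon, glat, _, _, st = _smooth_world(rng)
        grid, _ = spatial.krige(st, lons, lats, value_col="swc")
        for _, row in st.head(10).iterrows():
            i = np.argmin(np.abs(lats - row["lat"]))
            j = np.argmin(np.abs(lons - row["lon"]))
            assert grid[i, j] == row["swc"]

    def test_uniform_field(self, rng):
        lons, lats = spatial.make_grid(0, 2, 0, 2, 0.2)
        pts = pd.DataFrame({
            "lon": rng.uniform(0, 2, 20), "lat": rng.uniform(0, 2, 20), "value": 7.0,
        })
        grid, diag = spatial.krige(pts, lons, lats)
        assert np.allclose(grid, 7.0, atol=1e-6)

    def test_weights_sum_to_one(self, rng):
        lons, lats, *_, st = _smooth_world(rng, n_stations=30)
        _, diag = spatial.krige(st, lons, lats, value_col="swc")
        assert diag["max_weight_sum_deviation"] < 1e-6

    def test_beats_nearest_neighbor_on_smooth_field(self, rng):
        lons, lats, glon, glat, t_true, g, st = _smooth_world(rng, noise=0.0)
        truth = g(t_true)
        grid, _ = spatial.krige(st, lons, lats, value_col="swc")
        rmse_k = np.sqrt(np.mean((grid - truth) ** 2))
        tree = cKDTree(st[["lon", "lat"]].to_numpy())
        _, nn = tree.query(np.column_stack([glon.ravel(), glat.ravel()]), k=1)
        rmse_nn = np.sqrt(np.mean((st["swc"].to_numpy()[nn].reshape(glon.shape) - truth) ** 2))
        assert rmse_k < rmse_nn

    def test_too_few_stations_rejected(self, rng):
        pts = pd.DataFrame({"lon": rng.uniform(0, 1, 10), "lat": rng.uniform(0, 1, 10), "value": 1.0})
        with pytest.raises(ValueError, match="13"):
            spatial.krige(pts, *spatial.make_grid(0, 1, 0, 1, 0.5))

    def test_duplicate_coordinates_rejected(self, rng):
        pts = pd.DataFrame({"lon": np.zeros(14), "lat": np.zeros(14), "value": 1.0})
        with pytest.raises(ValueError, match="duplicate"):
            spatial.krige(pts, *spatial.make_grid(0, 1, 0, 1, 0.5))


class TestPolynomialCorrection:
    def test_recovers_known_quintic(self, rng):
        coef = np.array([50.0, -2.0, 0.8, -0.05, -0.004, 0.0002])
        true_poly = np.polynomial.Polynomial(coef)
        t = rng.uniform(-5, 20, 80)
        y = true_poly(t) + rng.normal(0, 0.5, t.size)
        cp = spatial.fit_cp_polynomial(t, y)
        grid = np.linspace(-4, 19, 100)
        assert np.allclose(cp.poly(grid), true_poly(grid), atol=1.0)

    def test_zero_outside_valid_range(self, rng):
        t = rng.uniform(0, 15, 40)
        y = 100 - (t - 7.0) ** 2 * 2  # negative beyond ~±7 of the peak
        cp = spatial.fit_cp_polynomial(t, y)
        lo, hi = cp.valid_range
        assert cp(lo - 1.0) == 0.0 and cp(hi + 1.0) == 0.0

    def test_negative_polynomial_floored_inside_range(self):
        poly = np.polynomial.Polynomial([-1.0, 0.0, 1.0])  # negative near 0
        cp = spatial.PolynomialCorrection(poly, valid_range=(-10.0, 10.0))
        assert cp(0.0) == 0.0
        assert cp(2.0) == pytest.approx(3.0)

    def test_narrow_span_rejected(self, rng):
        t = rng.uniform(5.0, 7.0, 40)
        with pytest.raises(ValueError, match="span"):
            spatial.fit_cp_polynomial(t, t * 2)

    def test_too_few_stations_rejected(self, rng):
        t = rng.uniform(0, 20, 10)
        with pytest.raises(ValueError, match="stations"):
            spatial.fit_cp_polynomial(t, t)


class TestCorrection:
    def test_zero_tdiff_is_identity(self, rng):
        lons, lats, glon, glat, t_true, g, st = _smooth_world(rng)
        surf, _ = spatial.build_surface(st, lons, lats, t_highres=None)
        surf.t_highres = surf.t_interp.copy()
        surf.t_diff = np.zeros_like(surf.t_interp)
        cp = spatial.fit_cp_polynomial(st["t_mean"], st["swc"])
        surf = spatial.correct_surface(surf, cp)
        assert np.allclose(surf.swc_corr, np.maximum(surf.swc_int, 0.0))

    def test_warm_cell_in_decreasing_regime_corrects_down(self, rng):
        lons, lats, glon, glat, t_true, g, st = _smooth_world(rng)
        cp = spatial.fit_cp_polynomial(st["t_mean"], st["swc"])
        surf, _ = spatial.build_surface(st, lons, lats, t_highres=t_true)
        # pick a cell where the fitted relation is locally decreasing
        t0 = surf.t_interp.copy()
        decreasing = cp(t0 + 0.1) < cp(t0) - 1e-9
        surf.t_diff = np.full_like(t0, 2.0)
        surf = spatial.correct_surface(surf, cp)
        assert (surf.swc_corr[decreasing] <= surf.swc_int[decreasing] + 1e-9).all()

    def test_correction_reduces_rmse(self, rng):
        lons, lats, glon, glat, t_true, g, st = _smooth_world(rng)
        truth = g(t_true)
        surf, _ = spatial.build_surface(st, lons, lats, t_highres=t_true)
        cp = spatial.fit_cp_polynomial(st["t_mean"], st["swc"])
        surf = spatial.correct_surface(surf, cp)
        rmse_unc = np.sqrt(np.mean((surf.swc_int - truth) ** 2))
        rmse_cor = np.sqrt(np.mean((surf.swc_corr - truth) ** 2))
        assert rmse_cor <= 0.7 * rmse_unc

    def test_shape_mismatch_rejected(self, rng):
        lons, lats, *_, st = _smooth_world(rng)
        surf, _ = spatial.build_surface(st, lons, lats)
        with pytest.raises(ValueError, match="t_diff"):
            spatial.correct_surface(surf, spatial.PolynomialCorrection(
                np.polynomial.Polynomial([1.0]), (-100, 100)))


class TestMasks:
    @staticmethod
    def _toy_surface():
        lons = np.array([0.0, 3.0, 6.0])
        lats = np.array([0.0])
        zeros = np.zeros((1, 3))
        return spatial.ChillSurface(
            lons=lons, lats=lats, swc_int=zeros, t_interp=zeros,
            t_highres=np.array([[10.0, 25.0, -5.0]]),
        )

    def test_distance_and_temperature_rules(self):
        surf = self._toy_surface()
        st = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        surf = spatial.mask_surface(surf, st)
        assert surf.mask_distance.tolist() == [[False, False, True]]  # 6° > 5°
        assert surf.mask_temperature.tolist() == [[False, True, True]]  # 25 °C and −5 °C
        assert surf.combined_mask.tolist() == [[False, True, True]]

    def test_mask_monotone_in_station_set(self):
        surf = self._toy_surface()
        one = spatial.mask_surface(self._toy_surface(), pd.DataFrame({"lon": [0.0], "lat": [0.0]}))
        two = spatial.mask_surface(self._toy_surface(), pd.DataFrame({"lon": [0.0, 6.0], "lat": [0.0, 0.0]}))
        assert not (two.mask_distance & ~one.mask_distance).any()


def test_netcdf_roundtrip(tmp_path, rng):
    lons, lats, glon, glat, t_true, g, st = _smooth_world(rng, n_stations=20)
    surf, _ = spatial.build_surface(st, lons, lats, t_highres=t_true)
    cp = spatial.fit_cp_polynomial(st["t_mean"], st["swc"])
    surf = spatial.correct_surface(surf, cp)
    surf = spatial.mask_surface(surf, st)
    path = tmp_path / "surface.nc"
    surf.to_netcdf(path)
    rl, rlat, vals = spatial.read_temperature_raster(path)
    assert vals.shape == (len(lats), len(lons))
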