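"""Derived environmental layers, matching and the collinearity screen."""
import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sealhab import envstack, synth
from sealhab.envstack import (
    collinearity_screen,
    compute_eke,
    compute_gradient,
    compute_slope,
    distance_to_ice_edge,
    match_covariates,
    regrid,
)
from sealhab.geo import GridSpec, haversine_km

KM = 111.32


class TestSlope:
    def test_constant_field_zero_slope(self):
        lat = np.linspace(-1, 1, 20)
        s = compute_slope(np.full((20, 20), -500.0), lat, 0.1)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_planar_ramp_matches_analytic(self):
        # 1 m rise per 1000 m northward at the equator
        cell = 0.1
        lat = np.linspace(-1, 1, 21)
        dy_m = cell * KM * 1000
        z = np.arange(21)[:, None] * (0.001 * dy_m) * np.ones((1, 21))
        s = compute_slope(z, lat, cell)
        expected = np.degrees(np.arctan(0.001))
        np.testing.assert_allclose(s[5:-5, 5:-5], expected, rtol=0.02)

    def test_agrees_with_central_differences_on_smooth_field(self):
        cell = 0.1
        lat = np.linspace(-65, -63, 21)
        x = np.arange(21)
        z = 200 * np.sin(x[:, None] / 4.0) * np.cos(x[None, :] / 5.0) - 1000
        s = compute_slope(z, lat, cell)
        dy_m = cell * KM * 1000
        dx_m = dy_m * np.cos(np.radians(lat))[:, None]
        gy, gx = np.gradient(z)
        ref = np.degrees(np.arctan(np.hypot(gx / dx_m, gy / dy_m)))
        inner = (slice(2, -2), slice(2, -2))
        assert np.nanmax(np.abs(s[inner] - ref[inner]) / np.abs(ref[inner])) < 0.10

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_slope(np.full((5, 5), np.nan), np.zeros(5), 0.1)

    def test_slope_range_invariant(self, small_stack):
        s = small_stack["slp"].values
        fin = np.isfinite(s)
        assert (s[fin] >= 0).all() and (s[fin] < 90).all()


class TestGradient:
    def test_constant_sst_zero_gradient(self):
        g = compute_gradient(np.full((10, 10), 1.5), np.zeros(10), 0.1)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_linear_front_constant_along_front(self):
        lat = np.zeros(15)
        sst = np.arange(15)[None, :] * np.ones((15, 1)) * 0.5
        g = compute_gradient(sst, lat, 0.1)
        inner = g[2:-2, 2:-2]
        np.testing.assert_allclose(inner, inner[0, 0], rtol=1e-6)

    def test_sharper_front_larger_gradient(self):
        lat = np.zeros(15)
        mild = compute_gradient(np.tanh((np.arange(15) - 7)[None, :] / 4.0) * np.ones((15, 1)), lat, 0.1)
        sharp = compute_gradient(np.tanh((np.arange(15) - 7)[None, :] / 1.0) * np.ones((15, 1)), lat, 0.1)
        assert np.nanmax(sharp) > np.nanmax(mild)


class TestEke:
    @pytest.mark.parametrize("u,v,expected", [(0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (3.0, 4.0, 12.5)])
    def test_closed_form(self, u, v, expected):
        out = compute_eke(np.full((3, 3), u), np.full((3, 3), v))
        np.testing.assert_allclose(out, expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_eke(np.zeros((3, 3)), np.zeros((4, 3)))


class TestIceEdgeDistance:
    GRID = GridSpec(lon0=-62.0, lat0=-65.0, cell=0.1, nlon=12, nlat=12)

    def test_ice_cell_has_zero_distance(self):
        sic = np.zeros((12, 12))
        sic[3, 3] = 0.2
        d = distance_to_ice_edge(sic, np.zeros((12, 12), bool), self.GRID)
        assert d[3, 3] == 0.0

    def test_adjacent_cell_one_step_distance(self):
        sic = np.zeros((12, 12))
        sic[3, 3] = 0.5
        d = distance_to_ice_edge(sic, np.zeros((12, 12), bool), self.GRID)
        lon1, lat1 = self.GRID.cell_center(3, 3)
        lon2, lat2 = self.GRID.cell_center(3, 4)
        np.testing.assert_allclose(d[3, 4], haversine_km(lon1, lat1, lon2, lat2))

    def test_land_is_missing_and_blocks_paths(self):
        sic = np.zeros((12, 12))
        sic[0, 0] = 0.5
        land = np.zeros((12, 12), bool)
        land[:, 5] = True  # wall: cells right of the wall unreachable
        d = distance_to_ice_edge(sic, land, self.GRID)
        assert np.isnan(d[:, 5]).all()
        assert np.isnan(d[5, 8])

    def test_no_ice_all_missing(self):
        d = distance_to_ice_edge(np.zeros((12, 12)), np.zeros((12, 12), bool), self.GRID)
        assert np.isnan(d).all()

    def test_matches_dijkstra_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        grid = GridSpec(lon0=-62.0, lat0=-65.0, cell=0.1, nlon=15, nlat=15)
        for _ in range(5):
            land = rng.uniform(size=(15, 15)) < 0.2
            sic = np.where(rng.uniform(size=(15, 15)) < 0.1, 0.5, 0.0)
            d = distance_to_ice_edge(sic, land, grid)
            G = nx.Graph()
            sea = ~land
            for i in range(15):
                for j in range(15):
                    if not sea[i, j]:
                        continue
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if (di, dj) != (0, 0) and 0 <= ii < 15 and 0 <= jj < 15 and sea[ii, jj]:
                                w = haversine_km(*grid.cell_center(i, j), *grid.cell_center(ii, jj))
                                G.add_edge((i, j), (ii, jj), weight=float(w))
            sources = [tuple(x) for x in np.argwhere(sea & (sic > 0.15))]
            if sources:
                dist = nx.multi_source_dijkstra_path_length(G, [s for s in sources if s in G], weight="weight")
            else:
                dist = {}
            for i in range(15):
                for j in range(15):
                    if land[i, j]:
                        assert np.isnan(d[i, j])
                    elif sea[i, j] and sic[i, j] > 0.15:
                        assert d[i, j] == 0.0
                    elif (i, j) in dist:
                        np.testing.assert_allclose(d[i, j], dist[(i, j)], rtol=1e-9)
                    elif sources:
                        assert np.isnan(d[i, j]) or not np.isfinite(d[i, j])


def _layer(values, lons, lats):
    return xr.DataArray(values, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))


class TestRegrid:
    def test_identity_on_same_grid(self):
        lons = np.arange(5) * 0.1
        lats = np.arange(5) * 0.1 - 65
        da = _layer(np.random.default_rng(0).normal(size=(5, 5)), lons, lats)
        out = regrid(da, lons, lats)
        np.testing.assert_allclose(out.values, da.values, atol=1e-12)

    def test_midpoint_is_average(self):
        da = _layer(np.array([[0.0, 1.0], [0.0, 1.0]]), np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        out = regrid(da, np.array([0.5]), np.array([0.5]))
        np.testing.assert_allclose(out.values, 0.5)

    def test_exact_on_affine_fields(self):
        rng = np.random.default_rng(1)
        lons = np.linspace(0, 2, 11)
        lats = np.linspace(-66, -64, 11)
        a, b, c = rng.normal(size=3)
        da = _layer(a + b * lats[:, None] + c * lons[None, :], lons, lats)
        tl = np.linspace(0.05, 1.9, 7)
        tla = np.linspace(-65.9, -64.1, 7)
        out = regrid(da, tl, tla)
        np.testing.assert_allclose(out.values, a + b * tla[:, None] + c * tl[None, :], rtol=1e-10)

    def test_disjoint_grids_rejected(self):
        da = _layer(np.zeros((3, 3)), np.arange(3) * 0.1, np.arange(3) * 0.1)
        with pytest.raises(ValueError):
            regrid(da, np.array([50.0]), np.array([50.0]))


def _match_stack(values_by_var, nlat=10, nlon=10):
    grid = GridSpec(lon0=-62.0, lat0=-65.0, cell=0.1, nlon=nlon, nlat=nlat)
    coords = {"time": pd.date_range("2019-03-01", periods=2), "lat": grid.lat_centers, "lon": grid.lon_centers}
    data = {"land": (("lat", "lon"), np.zeros((nlat, nlon), bool))}
    for name, v in values_by_var.items():
        data[name] = (("time", "lat", "lon"), np.broadcast_to(v, (2, nlat, nlon)).copy())
    ds = xr.Dataset(data, coords=coords, attrs={"cell_deg": 0.1, "lon0": -62.0, "lat0": -65.0})
    return ds, grid


class TestMatchCovariates:
    def test_uniform_field_gives_constant(self):
        ds, grid = _match_stack({"sst": np.full((10, 10), 1.7)})
        rec = pd.DataFrame({"date": ["2019-03-01"], "row": [5], "col": [5]})
        out = match_covariates(rec, ds, radius_km=15, covariates=["sst"])
        np.testing.assert_allclose(out["sst"], 1.7)

    def test_tiny_radius_gives_own_cell(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        ds, grid = _match_stack({"sst": vals})
        rec = pd.DataFrame({"date": ["2019-03-01"], "row": [4], "col": [7]})
        out = match_covariates(rec, ds, radius_km=2, covariates=["sst"])
        np.testing.assert_allclose(out["sst"], vals[4, 7])

    def test_two_cell_mean(self):
        vals = np.full((10, 10), np.nan)
        vals[5, 5] = 2.0
        vals[5, 6] = 4.0
        ds, grid = _match_stack({"sst": vals})
        rec = pd.DataFrame({"date": ["2019-03-01"], "row": [5], "col": [5]})
        # radius that captures exactly the east-west neighbours (lon spacing
        # ~4.7 km at -64.5) but values exist only in the two cells
        out = match_covariates(rec, ds, radius_km=6, covariates=["sst"])
        np.testing.assert_allclose(out["sst"], 3.0)

    def test_order_invariance_and_bounds(self, small_stack, reg_tracks):
        from sealhab import pseudoabs

        grid = synth.grid_of(small_stack)
        g = pseudoabs.grid_locations(reg_tracks, [], grid)
        skel = pseudoabs.sample_balanced(g, grid, seed=0).head(40)
        a = match_covariates(skel, small_stack)
        b = match_covariates(skel.iloc[::-1].reset_index(drop=True), small_stack).iloc[::-1].reset_index(drop=True)
        for c in ["sst", "bat"]:
            np.testing.assert_allclose(a[c].to_numpy(), b[c].to_numpy())
        assert a["sst"].min() >= np.nanmin(small_stack["sst"].values) - 1e-9
        assert a["sst"].max() <= np.nanmax(small_stack["sst"].values) + 1e-9

    def test_date_outside_stack_rejected(self, small_stack):
        rec = pd.DataFrame({"date": ["2030-01-01"], "row": [5], "col": [5]})
        with pytest.raises(ValueError):
            match_covariates(rec, small_stack)


class TestCollinearityScreen:
    def test_duplicate_covariate_dropped(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"sst": rng.normal(size=100)})
        t["sit"] = t["sst"]
        t["sal"] = rng.normal(size=100)
        rep = collinearity_screen(t, covariates=["sit", "sst", "sal"])
        assert any(d[0] == "sst" or d[0] == "sit" for d in rep["dropped"])
        assert len(rep["kept"]) == 2

    def test_independent_covariates_nothing_dropped(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({c: rng.normal(size=200) for c in ["sst", "sal", "chl"]})
        rep = collinearity_screen(t)
        assert rep["dropped"] == []

    def test_sit_dropped_against_sic_on_synthetic_stack(self):
        rng = np.random.default_rng(2)
        sic = rng.uniform(0, 1, 300)
        t = pd.DataFrame({"sic": sic, "sit": 1.8 * sic**1.5 + rng.normal(0, 0.02, 300), "sst": rng.normal(size=300)})
        rep = collinearity_screen(t)
        assert ("sit", "sic") in [(d[0], d[1]) for d in rep["dropped"]]
        assert "sic" in rep["kept"]

    def test_constant_covariate_reported_not_dropped(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"sst": rng.normal(size=50), "sal": np.ones(50)})
        rep = collinearity_screen(t)
        assert "sal" in rep["undefined"]
        assert "sal" in rep["kept"]


def test_derived_layer_invariants(small_stack):
    eke = small_stack["eke"].values
    assert np.nanmin(eke) >= 0
    edge = small_stack["edge"].values
    assert np.nanmin(edge) >= 0
    assert small_stack["chl"].attrs.get("log1p") and small_stack["eke"].attrs.get("log1p")
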