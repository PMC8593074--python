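"""Environmental covariate stack: derived layers, regridding, matching.

The modelling covariates, in canonical order: BAT (bathymetry, m, negative
at sea), SLP (seabed slope, deg), SIC (sea-ice fraction), EDGE (distance to
the 15% ice edge, km), SIT (ice thickness, m), SST (deg C), SSTg (SST
gradient, deg), SAL (PSU), SALg (salinity gradient, deg), SSH (m), EKE
(eddy kinetic energy, m2 s-2, stored log(x+1)), CHL (chlorophyll-a,
mg m-3, stored log(x+1)) and MLD (mixed-layer depth, m).  Slope-style
gradients use Horn's eight-neighbour method with latitude-corrected cell
dimensions; EDGE is a shortest-path distance through sea cells only.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import spearmanr

from .geo import GridSpec, haversine_km
from .synth import grid_of

log = logging.getLogger(__name__)

COVARIATE_ORDER = ["bat", "slp", "sic", "edge", "sit", "sst", "sstg", "sal", "salg", "ssh", "eke", "chl", "mld"]

KM_PER_DEG = 111.32


def _horn_slope(z: np.ndarray, lat_centers: np.ndarray, cell_deg: float) -> np.ndarray:
    """Horn's method slope in degrees on a geographic grid.

    Edge cells use the available neighbours (edge replication); cells with
    missing neighbours fall back to the centre value for those neighbours.
    """
    if np.all(~np.isfinite(z)):
        raise ValueError("all-missing raster")
    # neighbours via edge replication; NaN neighbours fall back to the centre
    zp = np.pad(z, 1, mode="edge")
    nb = {}
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            block = zp[1 + di : zp.shape[0] - 1 + di, 1 + dj : zp.shape[1] - 1 + dj]
            nb[(di, dj)] = np.where(np.isfinite(block), block, z)
    dy_m = cell_deg * KM_PER_DEG * 1000.0
    dx_m = cell_deg * KM_PER_DEG * 1000.0 * np.cos(np.radians(lat_centers))[:, None]
    dzdx = (
        (nb[(-1, 1)] + 2 * nb[(0, 1)] + nb[(1, 1)]) - (nb[(-1, -1)] + 2 * nb[(0, -1)] + nb[(1, -1)])
    ) / (8.0 * dx_m)
    dzdy = (
        (nb[(1, -1)] + 2 * nb[(1, 0)] + nb[(1, 1)]) - (nb[(-1, -1)] + 2 * nb[(-1, 0)] + nb[(-1, 1)])
    ) / (8.0 * dy_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~np.isfinite(z)] = np.nan
    return slope


def compute_slope(bat: np.ndarray, lat_centers: np.ndarray, cell_deg: float) -> np.ndarray:
    """Seabed slope (degrees) from bathymetry."""
    return _horn_slope(np.asarray(bat, float), lat_centers, cell_deg)


def compute_gradient(layer: np.ndarray, lat_centers: np.ndarray, cell_deg: float) -> np.ndarray:
    """Spatial gradient of a scalar field expressed as a slope in degrees
    (same operator as the seabed slope, applied to e.g. SST or SAL)."""
    return _horn_slope(np.asarray(layer, float), lat_centers, cell_deg)


def compute_eke(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Eddy kinetic energy 0.5 (U^2 + V^2), m2 s-2 (untransformed)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("U and V must be co-registered (same shape)")
    return 0.5 * (u**2 + v**2)


def distance_to_ice_edge(
    sic: np.ndarray,
    land: np.ndarray,
    grid: GridSpec,
    threshold: float = 0.15,
) -> np.ndarray:
    """Shortest-path distance (km) from each open-water cell to the nearest
    ice cell (SIC > threshold), travelling through sea cells only
    (8-connected, great-circle edge lengths).  Ice cells get 0; land is NaN;
    if no ice exists anywhere, all distances are NaN (logged)."""
    sic = np.asarray(sic, float)
    land = np.asarray(land, bool)
    nlat, nlon = sic.shape
    sea = ~land
    ice = sea & (sic > threshold)
    out = np.full(sic.shape, np.nan)
    if not ice.any():
        log.info("no cells above the ice threshold; EDGE undefined everywhere")
        return out
    idx = -np.ones(sic.shape, dtype=int)
    sea_i, sea_j = np.nonzero(sea)
    idx[sea_i, sea_j] = np.arange(len(sea_i))
    n_sea = len(sea_i)
    lonc, latc = grid.cell_center(sea_i, sea_j)
    rows, cols, wts = [], [], []
    for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):  # undirected: half the offsets
        ii, jj = sea_i + di, sea_j + dj
        ok = (ii >= 0) & (ii < nlat) & (jj >= 0) & (jj < nlon)
        ok[ok] &= sea[ii[ok], jj[ok]]
        a = idx[sea_i[ok], sea_j[ok]]
        b = idx[ii[ok], jj[ok]]
        lon2, lat2 = grid.cell_center(ii[ok], jj[ok])
        w = haversine_km(lonc[ok], latc[ok], lon2, lat2)
        rows.extend([a, b])
        cols.extend([b, a])
        wts.extend([w, w])
    # virtual supersource (node n_sea) wired to every ice cell at zero cost
    ice_nodes = idx[ice]
    rows.append(np.full(len(ice_nodes), n_sea))
    cols.append(ice_nodes)
    wts.append(np.zeros(len(ice_nodes)))
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))), shape=(n_sea + 1, n_sea + 1)
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=n_sea)
    d = dist[:n_sea]
    d[~np.isfinite(d)] = np.nan  # sea cells unreachable from any ice
    out[sea_i, sea_j] = d
    return out


def regrid(layer: xr.DataArray, target_lon: np.ndarray, target_lat: np.ndarray) -> xr.DataArray:
    """Bilinear interpolation onto target cell-centre coordinates.

    Missing source cells propagate missing; target points outside the source
    extent are missing; fully disjoint grids are rejected.
    """
    src_lon = layer["lon"].values
    src_lat = layer["lat"].values
    if target_lon.max() < src_lon.min() or target_lon.min() > src_lon.max() or (
        target_lat.max() < src_lat.min() or target_lat.min() > src_lat.max()
    ):
        raise ValueError("source and target grids are disjoint")
    return layer.interp(lon=target_lon, lat=target_lat, method="linear")


def add_derived_layers(stack: xr.Dataset, ice_threshold: float = 0.15) -> xr.Dataset:
    """Add SLP, SSTg, SALg, EDGE, EKE and apply the log(x+1) transforms.

    EKE and CHL are stored log(x+1)-transformed, marked in layer attrs so the
    transform is never applied twice.
    """
    stack = stack.copy()
    grid = grid_of(stack)
    lat = grid.lat_centers
    cell = grid.cell
    stack["slp"] = (("lat", "lon"), compute_slope(stack["bat"].values, lat, cell))
    land = stack["land"].values
    T = stack.sizes["time"]
    sstg = np.empty((T, grid.nlat, grid.nlon))
    salg = np.empty_like(sstg)
    edge = np.empty_like(sstg)
    for t in range(T):
        sstg[t] = compute_gradient(stack["sst"].values[t], lat, cell)
        salg[t] = compute_gradient(stack["sal"].values[t], lat, cell)
        edge[t] = distance_to_ice_edge(stack["sic"].values[t], land, grid, ice_threshold)
    stack["sstg"] = (("time", "lat", "lon"), sstg)
    stack["salg"] = (("time", "lat", "lon"), salg)
    stack["edge"] = (("time", "lat", "lon"), edge)
    eke = compute_eke(stack["u"].values, stack["v"].values)
    stack["eke"] = (("time", "lat", "lon"), np.log1p(eke))
    stack["eke"].attrs["log1p"] = True
    if not stack["chl"].attrs.get("log1p", False):
        stack["chl"] = np.log1p(stack["chl"])
        stack["chl"].attrs["log1p"] = True
    return stack


def match_covariates(
    records: pd.DataFrame,
    stack: xr.Dataset,
    radius_km: float = 15.0,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Attach covariates to presence/absence records.

    Each record receives, per covariate, the mean over grid cells whose
    centres lie within ``radius_km`` great-circle km of the record's cell
    centre (ties exactly at the radius included), from the same UTC date's
    layer (static layers are date-free).  Missing cells are ignored in the
    mean; an all-missing neighbourhood yields a missing value (tolerated for
    CHL downstream).
    """
    covariates = covariates or [c for c in COVARIATE_ORDER if c in stack.data_vars]
    grid = grid_of(stack)
    dates = pd.DatetimeIndex(stack.time.values)
    rec_dates = pd.to_datetime(records["date"])
    if rec_dates.min() < dates[0] or rec_dates.max() > dates[-1]:
        bad = records[(rec_dates < dates[0]) | (rec_dates > dates[-1])]
        raise ValueError(f"records outside the stack's date range: {bad.index.tolist()[:10]}")
    if (records["row"].min() < 0) or (records["row"].max() >= grid.nlat) or (
        records["col"].min() < 0 or records["col"].max() >= grid.nlon
    ):
        raise ValueError("records outside the stack extent")

    # neighbourhood offsets per latitude row (lon spacing shrinks poleward)
    max_dr = int(np.floor(radius_km / (KM_PER_DEG * grid.cell))) + 1
    offsets_by_row: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def offsets(row: int):
        if row not in offsets_by_row:
            lon_c, lat_c = grid.cell_center(row, 0)
            max_dc = int(np.ceil(radius_km / (KM_PER_DEG * grid.cell * max(np.cos(np.radians(lat_c)), 1e-6)))) + 1
            dr, dc = np.meshgrid(np.arange(-max_dr, max_dr + 1), np.arange(-max_dc, max_dc + 1), indexing="ij")
            lon_n, lat_n = grid.cell_center(row + dr, dc)  # dc relative: use lon offset from col 0
            d = haversine_km(lon_c, lat_c, lon_n, lat_n)
            ok = d <= radius_km
            offsets_by_row[row] = (dr[ok], dc[ok])
        return offsets_by_row[row]

    out = records.copy().reset_index(drop=True)
    arrs = {c: stack[c].values for c in covariates}
    static = {c: ("time" not in stack[c].dims) for c in covariates}
    time_index = {d: i for i, d in enumerate(dates)}
    vals = {c: np.full(len(out), np.nan) for c in covariates}
    rows_rec = out["row"].to_numpy()
    cols_rec = out["col"].to_numpy()
    t_idx = np.array([time_index[pd.Timestamp(d)] for d in pd.to_datetime(out["date"]).dt.normalize()])
    for i in range(len(out)):
        dr, dc = offsets(int(rows_rec[i]))
        rr = rows_rec[i] + dr
        cc = cols_rec[i] + dc
        ok = (rr >= 0) & (rr < grid.nlat) & (cc >= 0) & (cc < grid.nlon)
        rr, cc = rr[ok], cc[ok]
        for c in covariates:
            block = arrs[c][rr, cc] if static[c] else arrs[c][t_idx[i], rr, cc]
            block = block[np.isfinite(block.astype(float))] if block.dtype != bool else block
            vals[c][i] = np.mean(block.astype(float)) if len(block) else np.nan
    for c in covariates:
        out[c] = vals[c]
    return out


def collinearity_screen(table: pd.DataFrame, covariates: list[str] | None = None, threshold: float = 0.7):
    """Spearman collinearity screen.

    Computes all pairwise Spearman correlations on the matched table and
    greedily drops, for each pair with \\|rho\\| >= threshold, the covariate
    that comes later in the canonical order, until no pair exceeds the
    threshold.  Constant covariates have undefined correlations; they are
    reported but never dropped automatically.
    """
    covariates = covariates or [c for c in COVARIATE_ORDER if c in table.columns]
    if len(covariates) < 2 or len(table) < 3:
        raise ValueError("need >= 2 covariates and >= 3 records")
    X = table[covariates].to_numpy(float)
    with np.errstate(invalid="ignore"):
        rho = spearmanr(X, nan_policy="omit").statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    constant = [c for i, c in enumerate(covariates) if np.nanstd(X[:, i]) == 0]
    keep = list(covariates)
    dropped: list[tuple[str, str, float]] = []
    changed = True
    while changed:
        changed = False
        for a_i, a in enumerate(covariates):
            for b_i, b in enumerate(covariates):
                if a_i >= b_i or a not in keep or b not in keep:
                    continue
                r = rho[a_i, b_i]
                if np.isfinite(r) and abs(r) >= threshold:
                    keep.remove(b)  # b is later in canonical order
                    dropped.append((b, a, float(r)))
                    changed = True
    report = {
        "spearman": pd.DataFrame(rho, index=covariates, columns=covariates),
        "dropped": dropped,
        "kept": keep,
        "undefined": constant,
        "threshold": threshold,
    }
    return report
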