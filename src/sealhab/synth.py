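"""Synthetic study system: winter ocean rasters, seal movement and surveys.

Everything the downstream pipeline consumes can be generated here from a
seed, with a known ("true") habitat-preference model, so that filtering,
state-space regularization, pseudo-absence construction and the boosted-tree
habitat model can all be tested for recovery of a known truth.

The emulated system is a Southern Ocean shelf region in austral winter:
a handful of coastal haul-out sites on land to the north, sea ice advancing
equatorward from the south over the season, and juvenile male fur seals
alternating haul-out residency with at-sea foraging trips whose movement is
biased toward a known logistic suitability function of the environmental
fields.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .geo import GridSpec, haversine_km, planar_to_lonlat

RAW_DYNAMIC = ["sst", "sal", "sic", "sit", "ssh", "u", "v", "chl", "mld"]

ARGOS_CLASSES = ["3", "2", "1", "0", "A", "B", "Z"]


@dataclass
class ArgosNoiseSpec:
    """Argos location-class error model: isotropic positional error SD (km)
    and the relative frequency of each class.  Class Z fixes are invalid and
    carry arbitrary (large) error; they are discarded by the SDA filter."""

    sd_km: dict = field(
        default_factory=lambda: {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0, "Z": 30.0}
    )
    freq: dict = field(
        default_factory=lambda: {"3": 0.08, "2": 0.12, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.20, "Z": 0.05}
    )

    def __post_init__(self):
        if set(self.sd_km) != set(ARGOS_CLASSES) or set(self.freq) != set(ARGOS_CLASSES):
            raise ValueError("noise spec must cover classes 3,2,1,0,A,B,Z")
        if any(v <= 0 for v in self.sd_km.values()):
            raise ValueError("all class error SDs must be > 0")
        tot = sum(self.freq.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-6):
            raise ValueError("class frequencies must sum to 1")

    def scaled(self, factor: float) -> "ArgosNoiseSpec":
        """Return a copy with every error SD multiplied by ``factor``
        (floored at a nominal 1e-9 km so SDs stay positive)."""
        return ArgosNoiseSpec(
            sd_km={k: max(v * factor, 1e-9) for k, v in self.sd_km.items()}, freq=dict(self.freq)
        )


@dataclass
class SyntheticWorldConfig:
    """Geometry, calendar and forcing of the synthetic study region."""

    lon_min: float = -63.0
    lat_min: float = -66.0
    cell: float = 0.1
    nlon: int = 60
    nlat: int = 60
    start_date: str = "2019-03-01"
    n_days: int = 120
    seed: int = 0
    # spatial correlation length of the random fields, in degrees
    corr_len_deg: float = 0.5
    # day-to-day AR(1) persistence of the dynamic anomaly fields
    temporal_phi: float = 0.92
    # seasonal ice forcing: the 15% edge starts at ice_edge_lat0 and moves
    # ice_edge_amplitude_deg equatorward (northward) by the final day
    ice_edge_lat0: float = -66.5
    ice_edge_amplitude_deg: float = 2.5
    ice_edge_width_deg: float = 0.35
    sst_range: tuple = (-2.0, 4.0)
    sal_range: tuple = (33.0, 35.0)
    # land occupies latitudes above lat_max - land_strip_deg (a northern coast)
    land_strip_deg: float = 0.4
    # (lon, lat, radius_deg) circular islands
    islands: tuple = ((-61.8, -63.5, 0.15),)
    # coastal haul-out sites (on sea cells adjacent to the northern coast)
    haulout_lons: tuple = (-62.3, -60.6, -58.6)

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.nlon < 2 or self.nlat < 2:
            raise ValueError("degenerate grid: need at least 2x2 cells")
        if self.n_days < 2:
            raise ValueError("date range must span at least 2 days")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.lon_min, self.lat_min, self.cell, self.nlon, self.nlat)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def _smooth_field(rng: np.random.Generator, nlat: int, nlon: int, sigma_cells: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length sigma_cells."""
    f = gaussian_filter(rng.standard_normal((nlat, nlon)), sigma=max(sigma_cells, 1e-6), mode="nearest")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_env_stack(config: SyntheticWorldConfig, seed: int | None = None) -> xr.Dataset:
    """Generate the raw environmental stack on the common 0.1-degree grid.

    Daily layers: SST, SAL, SIC, SIT, SSH, U, V, CHL, MLD; static BAT and a
    boolean land mask.  SIC is in [0, 1] and its 15% contour moves
    equatorward over the simulated winter.  Derived layers (slope, gradients,
    EKE, distance-to-ice-edge, log transforms) are added by
    :func:`sealhab.envstack.add_derived_layers`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid
    lat = grid.lat_centers
    lon = grid.lon_centers
    lat2d = lat[:, None] * np.ones((1, grid.nlon))
    sigma = config.corr_len_deg / config.cell
    dates = config.dates
    T = len(dates)

    # land: northern strip plus islands
    land = lat2d > (grid.lat_max - config.land_strip_deg)
    for ilon, ilat, irad in config.islands:
        land |= ((lon[None, :] - ilon) ** 2 + (lat[:, None] - ilat) ** 2) < irad**2

    # static bathymetry: deeper offshore (south), smooth roughness; positive on land
    bat_anom = _smooth_field(rng, grid.nlat, grid.nlon, sigma)
    shelf = (lat2d - grid.lat_max) / (grid.lat_max - grid.lat0)  # 0 at coast, -1 at south edge
    bat = -300.0 + 2800.0 * shelf + 500.0 * bat_anom
    bat = np.clip(bat, -4500.0, -20.0)
    bat = np.where(land, 150.0, bat)

    # AR(1)-in-time standardized anomaly fields
    def anomaly_series() -> np.ndarray:
        out = np.empty((T, grid.nlat, grid.nlon))
        out[0] = _smooth_field(rng, grid.nlat, grid.nlon, sigma)
        phi = config.temporal_phi
        for t in range(1, T):
            out[t] = phi * out[t - 1] + math.sqrt(1.0 - phi**2) * _smooth_field(rng, grid.nlat, grid.nlon, sigma)
        return out

    frac_season = np.arange(T) / max(T - 1, 1)
    lat_norm = (lat2d - grid.lat0) / (grid.lat_max - grid.lat0)  # 0 south, 1 north

    sst_lo, sst_hi = config.sst_range
    sst = (
        sst_lo
        + (sst_hi - sst_lo) * lat_norm[None, :, :]
        - 1.0 * frac_season[:, None, None]  # seasonal cooling
        + 0.6 * anomaly_series()
    )

    sal_lo, sal_hi = config.sal_range
    sal = sal_lo + (sal_hi - sal_lo) * (0.5 + 0.25 * anomaly_series()) + 0.3 * (1 - lat_norm[None, :, :])
    sal = np.clip(sal, sal_lo - 1.0, sal_hi + 1.0)

    # sea ice: deterministic seasonal edge + a static spatial texture so that
    # zero seasonal amplitude yields day-invariant layers
    edge_lat = config.ice_edge_lat0 + config.ice_edge_amplitude_deg * frac_season
    sic_texture = 0.06 * _smooth_field(rng, grid.nlat, grid.nlon, sigma)
    sic = _logistic((edge_lat[:, None, None] - lat2d[None, :, :]) / config.ice_edge_width_deg)
    sic = np.clip(sic + sic_texture[None, :, :], 0.0, 1.0)
    sic[:, land] = 0.0

    # ice thickness: monotone in SIC plus small noise (collinear by design)
    sit = np.clip(1.8 * sic**1.5 + 0.03 * anomaly_series(), 0.0, None)

    ssh = -0.1 + 0.12 * anomaly_series()
    u = 0.08 * anomaly_series()
    v = 0.08 * anomaly_series()
    # chlorophyll: right-skewed, declining through winter
    chl = np.exp(0.9 * anomaly_series() - 1.2 - 1.0 * frac_season[:, None, None])
    mld = np.clip(60.0 + 35.0 * anomaly_series() + 40.0 * frac_season[:, None, None], 5.0, None)

    ds = xr.Dataset(
        data_vars={
            "bat": (("lat", "lon"), bat),
            "land": (("lat", "lon"), land),
            "sst": (("time", "lat", "lon"), sst),
            "sal": (("time", "lat", "lon"), sal),
            "sic": (("time", "lat", "lon"), sic),
            "sit": (("time", "lat", "lon"), sit),
            "ssh": (("time", "lat", "lon"), ssh),
            "u": (("time", "lat", "lon"), u),
            "v": (("time", "lat", "lon"), v),
            "chl": (("time", "lat", "lon"), chl),
            "mld": (("time", "lat", "lon"), mld),
        },
        coords={"time": dates, "lat": lat, "lon": lon},
        attrs={
            "cell_deg": config.cell,
            "lon0": grid.lon0,
            "lat0": grid.lat0,
            "islands_json": __import__("json").dumps([list(i) for i in config.islands]),
            "units": "BAT m (negative at sea), SST degC, SAL PSU, SIC fraction, SIT m, "
            "SSH m, U/V m s-1, CHL mg m-3, MLD m",
        },
    )
    for name in RAW_DYNAMIC + ["bat"]:
        arr = ds[name].values
        arr[..., land] = np.nan if name != "bat" else arr[..., land]
    return ds


def grid_of(stack: xr.Dataset) -> GridSpec:
    """Recover the GridSpec of a stack from its attrs/coords."""
    cell = float(stack.attrs["cell_deg"])
    return GridSpec(float(stack.attrs["lon0"]), float(stack.attrs["lat0"]), cell, stack.sizes["lon"], stack.sizes["lat"])


@dataclass
class TruthModel:
    """Known habitat-preference and movement model used to generate tracks.

    ``coefficients`` act on per-covariate standardized fields; suitability is
    the logistic of the linear predictor, hence always in [0, 1].  ``beta``
    scales the movement bias toward suitable habitat; beta = 0 yields an
    unbiased correlated random walk.
    """

    coefficients: dict = field(default_factory=lambda: {"sst": 2.0, "bat": -2.0, "sal": -2.0})
    intercept: float = 0.0
    beta: float = 0.0
    step_shape: float = 2.0
    step_scale_km: float = 10.0  # gamma scale; mean 6-h step = shape*scale
    turn_kappa: float = 0.6
    # haul-out schedule
    p_depart_per_evening_hour: float = 0.35
    trip_days_start: float = 3.0
    trip_days_end: float = 25.0
    trip_sigma: float = 0.5
    p_same_site: float = 0.15
    # candidate steps drawn per 6-h move; more candidates sharpen selection
    n_candidates: int = 15

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("preference strength beta must be >= 0")

    def suitability(self, stack: xr.Dataset) -> xr.DataArray:
        """True suitability in [0,1] on the stack's (time, lat, lon) grid."""
        missing = [c for c in self.coefficients if c not in stack.data_vars]
        if missing:
            raise ValueError(f"truth model references covariates absent from the world: {missing}")
        lp = None
        for name, coef in self.coefficients.items():
            layer = stack[name]
            mu = float(layer.mean(skipna=True))
            sd = float(layer.std(skipna=True)) or 1.0
            z = (layer - mu) / sd
            if "time" not in z.dims:
                z = z.expand_dims(time=stack.time).transpose("time", "lat", "lon")
            lp = coef * z if lp is None else lp + coef * z
        return 1.0 / (1.0 + np.exp(-(lp + self.intercept)))


def _sample_class(rng, noise: ArgosNoiseSpec) -> str:
    classes = list(noise.freq)
    p = np.array([noise.freq[c] for c in classes])
    return classes[rng.choice(len(classes), p=p / p.sum())]


def generate_tracks(
    stack: xr.Dataset,
    truth: TruthModel,
    n_individuals: int,
    noise: ArgosNoiseSpec | None = None,
    seed: int = 0,
    duration_range_days: tuple = (26, 197),
    obs_interval_mean_h: float = 1.8,
    n_dive_tagged: int = 0,
    step_hours: int = 6,
):
    """Simulate tagged seals: true 6-h paths plus irregular noisy Argos fixes.

    Returns ``(obs, true_paths, dives)`` DataFrames.  True paths never cross
    the land mask.  Movement is a correlated random walk among candidate
    steps weighted by exp(beta * suitability), alternating with haul-out
    residency at coastal sites (evening departures, morning arrivals).
    """
    noise = noise or ArgosNoiseSpec()
    rng = np.random.default_rng(seed)
    grid = grid_of(stack)
    land = stack["land"].values
    suit = truth.suitability(stack).values  # (time, lat, lon)
    dates = pd.DatetimeIndex(stack.time.values)
    t0 = dates[0]
    n_steps_day = 24 // step_hours

    # haul-out sites: first sea cell south of the northern coast at the
    # configured longitudes (tagging effort is coastal, as in real studies)
    sites = []
    for lon_site in _haulout_lons(stack):
        _, col = grid.to_cell(lon_site, grid.lat0 + grid.cell / 2)
        row = grid.nlat - 1
        while row >= 0 and land[row, col]:
            row -= 1
        if row >= 0:
            lon_c, lat_c = grid.cell_center(row, col)
            sites.append((float(lon_c), float(lat_c)))
    if not sites:
        raise ValueError("no sea cell available for a haul-out site")

    max_days = len(dates)
    obs_rows, true_rows, dive_rows = [], [], []

    for ind in range(n_individuals):
        iid = f"seal{ind:02d}"
        dur_lo, dur_hi = duration_range_days
        duration = min(int(rng.integers(dur_lo, dur_hi + 1)), max_days)
        start_day = int(rng.integers(0, max(max_days - duration, 0) + 1)) if max_days > duration else 0
        site_idx = int(rng.integers(len(sites)))
        lon_cur, lat_cur = sites[site_idx]
        heading = rng.uniform(0, 2 * np.pi)
        hauled = True
        trip_end_step = None
        target_site = None
        n_steps = duration * n_steps_day
        season_frac0 = start_day / max(max_days - 1, 1)

        path = []
        for k in range(n_steps):
            tcur = t0 + pd.Timedelta(hours=start_day * 24 + k * step_hours)
            day_idx = min((tcur - t0).days, max_days - 1)
            local_hour = (tcur.hour + lon_cur / 15.0) % 24.0
            if hauled:
                # evening departure window (local 17-23 h)
                if 17.0 <= local_hour <= 23.0 and rng.uniform() < truth.p_depart_per_evening_hour:
                    hauled = False
                    frac = (start_day + k / n_steps_day) / max(max_days - 1, 1)
                    mean_days = truth.trip_days_start + (truth.trip_days_end - truth.trip_days_start) * frac
                    trip_days = rng.lognormal(math.log(max(mean_days, 0.05)), truth.trip_sigma)
                    trip_end_step = k + max(int(round(trip_days * n_steps_day)), 1)
                    if rng.uniform() < truth.p_same_site:
                        target_site = site_idx
                    else:
                        target_site = int(rng.integers(len(sites)))
                path.append((tcur, lon_cur, lat_cur, not hauled))
                continue

            homing = trip_end_step is not None and k >= trip_end_step
            lon_cur, lat_cur, heading = _crw_step(
                rng, grid, land, suit[day_idx], lon_cur, lat_cur, heading, truth,
                homing_target=sites[target_site] if homing else None,
                n_candidates=truth.n_candidates,
            )
            # arrival: near the target site in the local morning
            if homing:
                d = haversine_km(lon_cur, lat_cur, *sites[target_site])
                local_hour = (tcur.hour + lon_cur / 15.0) % 24.0
                overdue = k > trip_end_step + 2 * n_steps_day
                if d < 12.0 and (4.0 <= local_hour <= 11.0 or overdue):
                    lon_cur, lat_cur = sites[target_site]
                    site_idx = target_site
                    hauled = True
                    trip_end_step = None
            path.append((tcur, lon_cur, lat_cur, not hauled))

        for tcur, lon_p, lat_p, at_sea in path:
            true_rows.append((iid, tcur, lon_p, lat_p, at_sea))

        # irregular Argos observations along the true path
        times = np.array([(p[0] - t0).total_seconds() for p in path])
        lons = np.array([p[1] for p in path])
        lats = np.array([p[2] for p in path])
        t_obs = times[0]
        while t_obs <= times[-1]:
            lon_o = float(np.interp(t_obs, times, lons))
            lat_o = float(np.interp(t_obs, times, lats))
            cls = _sample_class(rng, noise)
            sd_deg_lat = noise.sd_km[cls] / 111.32
            sd_deg_lon = noise.sd_km[cls] / (111.32 * math.cos(math.radians(lat_o)))
            obs_rows.append(
                (
                    iid,
                    t0 + pd.Timedelta(seconds=float(t_obs)),
                    lon_o + rng.normal(0.0, sd_deg_lon),
                    lat_o + rng.normal(0.0, sd_deg_lat),
                    cls,
                )
            )
            t_obs += max(rng.exponential(obs_interval_mean_h * 3600.0), 60.0)

        # dive records for depth-tagged individuals: deepest dives grow as
        # winter advances (krill moves deeper)
        if ind < n_dive_tagged:
            for d in range(duration):
                date = (t0 + pd.Timedelta(days=start_day + d)).normalize()
                frac = (start_day + d) / max(max_days - 1, 1)
                base = 35.0 + 45.0 * frac
                for _ in range(int(rng.integers(4, 9))):
                    depth = max(rng.normal(base * 0.7, base * 0.25), 2.0)
                    dive_rows.append((iid, date, float(min(depth, 185.0))))

    obs = pd.DataFrame(obs_rows, columns=["individual_id", "timestamp", "lon", "lat", "location_class"])
    obs = obs.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    true_paths = pd.DataFrame(true_rows, columns=["individual_id", "timestamp", "lon", "lat", "at_sea"])
    dives = pd.DataFrame(dive_rows, columns=["individual_id", "date", "depth_m"])
    return obs, true_paths, dives


def _haulout_lons(stack: xr.Dataset):
    lons = stack.attrs.get("haulout_lons")
    if lons is not None:
        return list(np.atleast_1d(lons))
    grid = grid_of(stack)
    return list(grid.lon0 + np.array([0.15, 0.5, 0.85]) * (grid.lon_max - grid.lon0))


def _crw_step(rng, grid, land, suit_day, lon, lat, heading, truth: TruthModel, homing_target=None, n_candidates=15):
    """One 6-h correlated-random-walk step with habitat bias.

    Candidate displacements are drawn from the step/turn distributions and
    weighted by exp(beta * suitability); homing adds a distance penalty
    toward the target haul-out.  Land and out-of-bounds candidates are
    rejected; if none survive, the seal holds position.
    """
    for widen in (1.0, 3.0):
        steps = rng.gamma(truth.step_shape, truth.step_scale_km, n_candidates)
        turns = rng.vonmises(0.0, truth.turn_kappa / widen, n_candidates)
        heads = heading + turns
        dx = steps * np.sin(heads)
        dy = steps * np.cos(heads)
        lon_c, lat_c = planar_to_lonlat(dx, dy, lon, lat)
        ok = grid.contains(lon_c, lat_c)
        if not ok.any():
            continue
        row, col = grid.to_cell(lon_c[ok], lat_c[ok])
        sea = ~land[row, col]
        if not sea.any():
            continue
        lon_c, lat_c, heads = lon_c[ok][sea], lat_c[ok][sea], heads[ok][sea]
        row, col = row[sea], col[sea]
        s = suit_day[row, col]
        s = np.where(np.isfinite(s), s, 0.0)
        logw = truth.beta * s
        if homing_target is not None:
            d = haversine_km(lon_c, lat_c, homing_target[0], homing_target[1])
            logw = logw - d / 10.0
        w = np.exp(logw - logw.max())
        i = rng.choice(len(w), p=w / w.sum())
        return float(lon_c[i]), float(lat_c[i]), float(heads[i])
    return lon, lat, heading


@dataclass
class TransectSurveyConfig:
    """Haul-out census design: per-haul-out expected totals split over
    censuses and transects, and the age-class composition."""

    haulouts: tuple = ("Baily Head", "Collins Point", "Whalers Bay")
    totals: tuple = (103, 281, 158)
    n_censuses: int = 2
    n_transects: int = 7
    class_probs: tuple = (0.497, 0.365, 0.137)  # juveniles, sub-adults, adults

    def __post_init__(self):
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class probabilities must be non-negative")
        if self.n_transects < 1 or len(self.haulouts) < 1:
            raise ValueError("need at least one haul-out and one transect")


def generate_transect_counts(config: TransectSurveyConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate transect counts of juveniles / sub-adults / adults."""
    rng = np.random.default_rng(seed)
    p = np.asarray(config.class_probs, dtype=float)
    p = p / p.sum() if p.sum() > 0 else p
    rows = []
    for h, total in zip(config.haulouts, config.totals):
        for census in range(config.n_censuses):
            census_total = total // config.n_censuses + (1 if census < total % config.n_censuses else 0)
            per_transect = rng.multinomial(census_total, np.full(config.n_transects, 1.0 / config.n_transects))
            for tr, n in enumerate(per_transect):
                if p.sum() > 0 and n > 0:
                    j, s, a = rng.multinomial(n, p)
                else:
                    j = s = a = 0
                rows.append((h, census + 1, tr + 1, int(j), int(s), int(a)))
    return pd.DataFrame(rows, columns=["haulout", "census", "transect", "juveniles", "subadults", "adults"])
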