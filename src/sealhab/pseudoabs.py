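"""Availability null model: simulated pseudo-tracks and the binomial table.

Pseudo-absences represent where a seal *could* have been given its movement
characteristics.  For each regularized track segment a first-order vector
autoregressive (VAR) model of (step length, sin turn, cos turn) is fitted
and used to simulate null tracks that share the template's start point and
timestamps, are confined to the sea, and are independent of the
environmental fields.  Presences and pseudo-absences are gridded daily at
0.1 degrees, contradictory pseudo-absences (adjacent in space and time to
any presence) are removed, and a 1:1 per-individual per-day stratified
sample is drawn.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import GridSpec, local_planar_km, planar_to_lonlat

log = logging.getLogger(__name__)


@dataclass
class MovementModel:
    """VAR(1) on z_t = (step length km, sin turn, cos turn):
    z_t = intercept + A z_{t-1} + eps, eps ~ N(0, cov)."""

    A: np.ndarray
    intercept: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        rho = np.max(np.abs(np.linalg.eigvals(self.A)))
        if rho >= 1.0:
            # project onto the stationary region, preserving direction
            self.A = self.A * (0.98 / rho)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


def _steps_and_turns(segment: pd.DataFrame) -> np.ndarray:
    """State series z_t = (L, sin turn, cos turn) from a regular segment."""
    lon = segment["lon"].to_numpy()
    lat = segment["lat"].to_numpy()
    x, y = local_planar_km(lon, lat, lon.mean(), lat.mean())
    dx = np.diff(x)
    dy = np.diff(y)
    L = np.hypot(dx, dy)
    heading = np.arctan2(dx, dy)
    turn = np.diff(heading)
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    z = np.column_stack([L[1:], np.sin(turn), np.cos(turn)])
    return z


def fit_movement_model(segment: pd.DataFrame) -> MovementModel:
    """Fit the VAR(1) movement model to a regularized segment (>= 10 steps)."""
    z = _steps_and_turns(segment)
    if len(z) < 9:  # 10 regular steps -> 9 usable state rows
        raise ValueError("segment too short: need >= 10 regular steps")
    Y = z[1:]
    X = np.column_stack([np.ones(len(z) - 1), z[:-1]])
    try:
        from statsmodels.tsa.api import VAR

        fit = VAR(z).fit(1, trend="c")
        A = fit.coefs[0]
        intercept = fit.intercept
        cov = np.atleast_2d(fit.sigma_u)
    except Exception:
        # degenerate (e.g. perfectly collinear) series: minimum-norm OLS
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        intercept = beta[0]
        A = beta[1:].T
        resid = Y - X @ beta
        cov = np.cov(resid.T) if len(resid) > 1 else np.zeros((3, 3))
        cov = np.atleast_2d(cov)
    return MovementModel(A=np.asarray(A, float), intercept=np.asarray(intercept, float), cov=np.asarray(cov, float))


def simulate_pseudo_tracks(
    model: MovementModel,
    template: pd.DataFrame,
    n: int = 50,
    grid: GridSpec | None = None,
    land: np.ndarray | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> list[pd.DataFrame]:
    """Simulate ``n`` null tracks with the template's timestamps, starting at
    the template's first location and restricted to sea cells.

    Each blocked step is re-drawn up to ``max_attempts`` times, then from a
    wider (inflated-covariance) proposal; a simulation that still cannot
    proceed is abandoned with a warning and replaced.
    """
    rng = np.random.default_rng(seed)
    ts = template["timestamp"].reset_index(drop=True)
    lon0 = float(template["lon"].iloc[0])
    lat0 = float(template["lat"].iloc[0])
    iid = template["individual_id"].iloc[0] if "individual_id" in template.columns else "sim"
    if grid is not None and land is not None:
        r0, c0 = grid.to_cell(lon0, lat0)
        if r0 >= 0 and land[r0, c0]:
            raise ValueError("template's first fix is not at sea")
    nsteps = len(ts)
    # chol of innovation covariance (guard semi-definiteness)
    cov = model.cov + np.eye(3) * 1e-12
    chol = np.linalg.cholesky(cov)

    def at_sea(lon, lat):
        if grid is None or land is None:
            return True
        if not grid.contains(lon, lat):
            return False
        r, c = grid.to_cell(lon, lat)
        return not land[r, c]

    sims = []
    guard = 0
    while len(sims) < n and guard < 10 * n:
        guard += 1
        lon = np.empty(nsteps)
        lat = np.empty(nsteps)
        lon[0], lat[0] = lon0, lat0
        # initial state from the template's own first step/turn
        z_tmpl = _steps_and_turns(template) if nsteps >= 3 else None
        z = z_tmpl[0].copy() if z_tmpl is not None and len(z_tmpl) else np.array([1.0, 0.0, 1.0])
        heading = rng.uniform(0, 2 * np.pi)
        failed = False
        for k in range(1, nsteps):
            placed = False
            for widen in (1.0, 3.0):
                for _ in range(max_attempts):
                    eps = widen * (chol @ rng.standard_normal(3))
                    z_new = model.intercept + model.A @ z + eps
                    L = max(z_new[0], 0.0)
                    s, c = z_new[1], z_new[2]
                    turn = np.arctan2(s, c) if (abs(s) + abs(c)) > 1e-12 else 0.0
                    h_new = heading + turn
                    x, y = L * np.sin(h_new), L * np.cos(h_new)
                    lon_new, lat_new = planar_to_lonlat(x, y, lon[k - 1], lat[k - 1])
                    if at_sea(float(lon_new), float(lat_new)):
                        lon[k], lat[k] = lon_new, lat_new
                        heading = h_new
                        z = z_new
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                failed = True
                break
        if failed:
            log.warning("pseudo-track simulation aborted at a blocked step; drawing a replacement")
            continue
        sims.append(
            pd.DataFrame(
                {"individual_id": iid, "sim": len(sims), "timestamp": ts, "lon": lon, "lat": lat}
            )
        )
    if len(sims) < n:
        raise RuntimeError("could not generate the requested number of pseudo-tracks")
    return sims


def grid_locations(
    real_tracks: pd.DataFrame,
    simulated_tracks: list[pd.DataFrame],
    grid: GridSpec,
) -> pd.DataFrame:
    """Grid presences (real tracks) and pseudo-absences (simulations) per
    individual per UTC date at the study grid's 0.1-degree cells.

    One record per (individual, date, cell, label); out-of-bounds positions
    are logged and dropped.
    """
    frames = []
    for label, dfs in (("presence", [real_tracks]), ("pseudo_absence", simulated_tracks)):
        for df in dfs:
            if len(df) == 0:
                continue
            row, col = grid.to_cell(df["lon"].to_numpy(), df["lat"].to_numpy())
            ok = row >= 0
            n_bad = int((~ok).sum())
            if n_bad:
                log.warning("%d %s positions outside the study grid dropped", n_bad, label)
            g = pd.DataFrame(
                {
                    "individual_id": df["individual_id"].to_numpy()[ok],
                    "date": pd.to_datetime(df["timestamp"]).dt.normalize().to_numpy()[ok],
                    "row": row[ok],
                    "col": col[ok],
                    "label": label,
                }
            )
            frames.append(g)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["individual_id", "date", "row", "col", "label"]
    )
    return out.drop_duplicates(["individual_id", "date", "row", "col", "label"]).reset_index(drop=True)


def filter_contradictions(gridded: pd.DataFrame, window_days: int = 2) -> pd.DataFrame:
    """Remove pseudo-absences whose cell is in the Moore neighbourhood
    (3x3 block, the cell itself included) of ANY individual's presence cell
    within +/- ``window_days`` days.  Presences are never removed."""
    pres = gridded[gridded["label"] == "presence"]
    pres_set = set(zip(pres["date"].astype("int64") // 86_400_000_000_000, pres["row"], pres["col"]))
    keep = np.ones(len(gridded), dtype=bool)
    days = gridded["date"].astype("int64").to_numpy() // 86_400_000_000_000
    rows = gridded["row"].to_numpy()
    cols = gridded["col"].to_numpy()
    is_pa = (gridded["label"] == "pseudo_absence").to_numpy()
    for i in np.nonzero(is_pa)[0]:
        d, r, c = days[i], rows[i], cols[i]
        hit = False
        for dd in range(-window_days, window_days + 1):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (d + dd, r + dr, c + dc) in pres_set:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        keep[i] = not hit
    return gridded[keep].reset_index(drop=True)


def sample_balanced(gridded: pd.DataFrame, grid: GridSpec, seed: int = 0) -> pd.DataFrame:
    """Within each (individual, date) stratum keep all presences and draw
    min(#presences, #pseudo-absences) pseudo-absences without replacement.

    Returns the presence/absence table skeleton (response, ids, cell centres).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for (iid, date), g in gridded.groupby(["individual_id", "date"], sort=True):
        p = g[g["label"] == "presence"]
        a = g[g["label"] == "pseudo_absence"]
        n_take = min(len(p), len(a))
        if len(p) and n_take < len(p):
            log.info("stratum (%s, %s): absence shortfall of %d", iid, date, len(p) - n_take)
        parts.append(p)
        if n_take:
            parts.append(a.iloc[rng.choice(len(a), size=n_take, replace=False)])
    if not parts:
        return pd.DataFrame(columns=["response", "individual_id", "date", "row", "col", "lon", "lat"])
    out = pd.concat(parts, ignore_index=True)
    lon, lat = grid.cell_center(out["row"].to_numpy(), out["col"].to_numpy())
    out["lon"] = lon
    out["lat"] = lat
    out["response"] = (out["label"] == "presence").astype(int)
    return out[["response", "individual_id", "date", "row", "col", "lon", "lat"]].reset_index(drop=True)
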