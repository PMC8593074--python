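"""Argos track cleaning, 6-hourly regularization and trip segmentation.

The cleaning chain mirrors standard pinniped-telemetry practice: drop
near-duplicate fixes (<= 2 min after the last kept fix), remove invalid
class-Z fixes and implausible fixes with a speed-distance-angle (SDA)
filter, split tracks at data gaps longer than 7 days, then regularize each
segment to a fixed 6-h time step with a correlated-random-walk state-space
model (Kalman filter + fixed-interval smoother, maximum-likelihood
parameters) that accounts for the Argos class-dependent measurement error.
Haul-out residency is detected by coastal proximity and trips are the
at-sea intervals in between.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geo import haversine_km, inner_angle_deg, local_planar_km, planar_to_lonlat
from .synth import ArgosNoiseSpec

log = logging.getLogger(__name__)

TRACK_COLS = ["individual_id", "timestamp", "lon", "lat", "location_class"]


def _check_sorted(track: pd.DataFrame) -> None:
    for _, g in track.groupby("individual_id", sort=False):
        if not g["timestamp"].is_monotonic_increasing:
            raise ValueError("track must be sorted by timestamp within individual")


def remove_near_duplicates(track: pd.DataFrame, window: pd.Timedelta = pd.Timedelta(minutes=2)) -> pd.DataFrame:
    """Drop fixes occurring <= ``window`` after the most recently *kept* fix
    of the same individual (sequential scan keeping the first of any run)."""
    _check_sorted(track)
    keep_idx = []
    for _, g in track.groupby("individual_id", sort=False):
        last_kept = None
        for idx, ts in zip(g.index, g["timestamp"]):
            if last_kept is None or (ts - last_kept) > window:
                keep_idx.append(idx)
                last_kept = ts
    return track.loc[keep_idx]


def _speed_pass(g: pd.DataFrame, vmax: float) -> pd.DataFrame:
    """Greedy forward scan dropping fixes implying speed > vmax (m/s) from
    the last kept fix."""
    lon = g["lon"].to_numpy()
    lat = g["lat"].to_numpy()
    t = g["timestamp"].astype("int64").to_numpy() / 1e9
    keep = [0]
    for i in range(1, len(g)):
        j = keep[-1]
        dt = t[i] - t[j]
        if dt <= 0:
            continue
        v = haversine_km(lon[j], lat[j], lon[i], lat[i]) * 1000.0 / dt
        if v <= vmax:
            keep.append(i)
    return g.iloc[keep]


def _spike_pass(g: pd.DataFrame, spike_rules) -> pd.DataFrame:
    """Remove internal fixes forming spikes: inner angle below a rule's angle
    with BOTH adjacent legs longer than that rule's length (km)."""
    changed = True
    while changed and len(g) >= 3:
        lon = g["lon"].to_numpy()
        lat = g["lat"].to_numpy()
        leg = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        ang = inner_angle_deg(lon[:-2], lat[:-2], lon[1:-1], lat[1:-1], lon[2:], lat[2:])
        bad = np.zeros(len(g), dtype=bool)
        for max_angle, min_leg in spike_rules:
            bad[1:-1] |= (ang < max_angle) & (leg[:-1] > min_leg) & (leg[1:] > min_leg)
        changed = bad.any()
        if changed:
            # remove the worst spike only, then re-evaluate geometry
            i = int(np.argmin(np.where(bad[1:-1], ang, np.inf))) + 1
            g = g.drop(g.index[i])
    return g


def sda_filter(
    track: pd.DataFrame,
    vmax: float = 3.0,
    spike_rules=((15.0, 2.5), (25.0, 5.0)),
) -> pd.DataFrame:
    """Speed-distance-angle filter.

    Removes all class-Z fixes, then iterates a greedy max-speed pass
    (``vmax`` m/s, great-circle) and a spike pass (inner angle < 15 deg with
    both legs > 2.5 km, or < 25 deg with both legs > 5 km) to a fixed point.
    The output is always a subsequence of the input.
    """
    _check_sorted(track)
    if "location_class" in track.columns:
        track = track[track["location_class"].astype(str) != "Z"]
    out = []
    for _, g in track.groupby("individual_id", sort=False):
        if len(g) < 2:
            out.append(g)
            continue
        prev_len = -1
        while len(g) != prev_len:
            prev_len = len(g)
            g = _speed_pass(g, vmax)
            g = _spike_pass(g, spike_rules)
        out.append(g)
    return pd.concat(out) if out else track


def split_on_gaps(track: pd.DataFrame, max_gap: pd.Timedelta = pd.Timedelta(days=7)) -> pd.DataFrame:
    """Assign ``segment_id`` so segments are maximal runs whose consecutive
    gaps are all <= ``max_gap`` ("in excess of" is strict)."""
    _check_sorted(track)
    parts = []
    for iid, g in track.groupby("individual_id", sort=False):
        gaps = g["timestamp"].diff()
        seg = (gaps > max_gap).cumsum()
        g = g.copy()
        g["segment_id"] = [f"{iid}-{s}" for s in seg]
        parts.append(g)
    return pd.concat(parts) if parts else track.assign(segment_id=pd.Series(dtype=str))


# ---------------------------------------------------------------------------
# correlated-random-walk state-space regularization


@dataclass
class CRWFit:
    gamma: float
    sigma_km: float
    converged: bool
    n_obs: int


def _ctcrw_mats(theta, sigma2, dt):
    """Transition and process-noise matrices of the continuous-time CRW
    (integrated Ornstein-Uhlenbeck velocity) over a step of ``dt`` hours."""
    e = math.exp(-theta * dt)
    F = np.array([[1.0, (1.0 - e) / theta], [0.0, e]])
    e2 = math.exp(-2.0 * theta * dt)
    q_vv = sigma2 * (1.0 - e2) / (2.0 * theta)
    q_xv = sigma2 * (1.0 - e) ** 2 / (2.0 * theta**2)
    q_xx = (sigma2 / theta**2) * (dt - 2.0 * (1.0 - e) / theta + (1.0 - e2) / (2.0 * theta))
    Q = np.array([[q_xx, q_xv], [q_xv, q_vv]]) + np.eye(2) * 1e-12
    return F, Q


def _ctcrw_kalman(times_h, y, obs_flag, r_var, theta, sigma2, compute_smooth=False):
    """Kalman filter (and optional RTS smoother) for the continuous-time CRW
    on one planar axis.

    ``times_h``: event times in hours (sorted); ``obs_flag`` marks events
    carrying an observation ``y`` with variance ``r_var`` (km^2); other
    events are prediction-only lattice points.  Returns (nll, smoothed
    means, smoothed covariances).
    """
    n = len(times_h)
    m = np.array([0.0, 0.0])
    first_obs = np.argmax(obs_flag)
    m[0] = y[first_obs]
    P = np.diag([max(r_var[first_obs], 1.0) * 4.0, sigma2 / (2.0 * theta) + 1.0])
    H = np.array([1.0, 0.0])
    nll = 0.0
    means_f = np.zeros((n, 2))
    covs_f = np.zeros((n, 2, 2))
    means_p = np.zeros((n, 2))
    covs_p = np.zeros((n, 2, 2))
    Fs = np.zeros((n, 2, 2))
    for t in range(n):
        if t > 0:
            dt = times_h[t] - times_h[t - 1]
            F, Q = _ctcrw_mats(theta, sigma2, max(dt, 1e-9))
            m = F @ m
            P = F @ P @ F.T + Q
            Fs[t] = F
        means_p[t], covs_p[t] = m, P
        if obs_flag[t]:
            S = P[0, 0] + r_var[t]
            K = P[:, 0] / S
            innov = y[t] - m[0]
            nll += 0.5 * (np.log(2 * np.pi * S) + innov**2 / S)
            m = m + K * innov
            P = P - np.outer(K, P[0, :])
        means_f[t], covs_f[t] = m, P
    if not compute_smooth:
        return nll, None, None
    ms = means_f.copy()
    Ps = covs_f.copy()
    for t in range(n - 2, -1, -1):
        G = covs_f[t] @ Fs[t + 1].T @ np.linalg.inv(covs_p[t + 1])
        ms[t] = means_f[t] + G @ (ms[t + 1] - means_p[t + 1])
        Ps[t] = covs_f[t] + G @ (Ps[t + 1] - covs_p[t + 1]) @ G.T
    return nll, ms, Ps


def fit_crw_ssm(
    segment: pd.DataFrame,
    step: pd.Timedelta = pd.Timedelta(hours=6),
    noise: ArgosNoiseSpec | None = None,
    min_sd_km: float = 1e-3,
) -> tuple[pd.DataFrame, CRWFit]:
    """Regularize one track segment to the fixed 6-h lattice.

    Maximum-likelihood CRW parameters (velocity persistence gamma, process
    SD sigma) are estimated by Kalman filtering on a local planar projection;
    positions and per-position uncertainty SDs come from the fixed-interval
    (RTS) smoother.  Observations keep their Argos-class measurement SD,
    inflated for their offset from the nearest lattice time.  Non-converged
    fits are retried from new starting values and flagged.
    """
    noise = noise or ArgosNoiseSpec()
    if len(segment) < 4:
        raise ValueError("segment needs >= 4 fixes")
    t = segment["timestamp"]
    span = t.iloc[-1] - t.iloc[0]
    if span < 2 * step:
        raise ValueError("segment must span at least two regular steps")
    n_lat = int(np.floor(span / step)) + 1
    t0 = t.iloc[0]
    lattice = t0 + step * np.arange(n_lat)

    lon_ref = segment["lon"].mean()
    lat_ref = segment["lat"].mean()
    x, y = local_planar_km(segment["lon"].to_numpy(), segment["lat"].to_numpy(), lon_ref, lat_ref)
    obs_h = (t - t0).dt.total_seconds().to_numpy() / 3600.0
    lattice_h = (step.total_seconds() / 3600.0) * np.arange(n_lat)
    if "location_class" in segment.columns:
        sd_obs = np.array([max(noise.sd_km.get(str(c), 10.0), min_sd_km) for c in segment["location_class"]])
    else:
        sd_obs = np.full(len(segment), 1.0)

    # merged event sequence: lattice (prediction-only) + observation events
    times_h = np.concatenate([lattice_h, obs_h])
    obs_flag = np.concatenate([np.zeros(n_lat, bool), np.ones(len(obs_h), bool)])
    yx = np.concatenate([np.zeros(n_lat), x])
    yy_ = np.concatenate([np.zeros(n_lat), y])
    r_var = np.concatenate([np.ones(n_lat), sd_obs**2])
    order = np.argsort(times_h, kind="stable")
    times_h, obs_flag, yx, yy_, r_var = times_h[order], obs_flag[order], yx[order], yy_[order], r_var[order]
    lattice_pos = np.nonzero(~obs_flag)[0]

    dts = np.diff(obs_h)
    dts = dts[dts > 0]
    med_dt = float(np.median(dts)) if len(dts) else 6.0
    speed_scale = max(
        (np.std(np.diff(x)) + np.std(np.diff(y))) / (2.0 * max(med_dt, 0.1)), 0.05
    )

    def nll(params):
        theta = math.exp(params[0])
        sigma2 = math.exp(params[1]) ** 2
        if not (1e-4 <= theta <= 1e3):
            return 1e12
        with np.errstate(all="ignore"):
            try:
                vx, _, _ = _ctcrw_kalman(times_h, yx, obs_flag, r_var, theta, sigma2)
                vy, _, _ = _ctcrw_kalman(times_h, yy_, obs_flag, r_var, theta, sigma2)
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e12
        val = vx + vy
        return val if np.isfinite(val) else 1e12

    best = None
    converged = False
    for th0, s0 in ((1.0 / 12.0, speed_scale), (1.0 / 3.0, speed_scale * 3), (1.0, speed_scale * 0.3)):
        res = minimize(
            nll,
            x0=[math.log(th0), math.log(max(s0, 1e-3))],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            best = res if res.fun <= best.fun else best
            break
    theta = math.exp(best.x[0])
    sigma = float(math.exp(best.x[1]))
    sigma2 = sigma**2
    _, msx, Psx = _ctcrw_kalman(times_h, yx, obs_flag, r_var, theta, sigma2, compute_smooth=True)
    _, msy, Psy = _ctcrw_kalman(times_h, yy_, obs_flag, r_var, theta, sigma2, compute_smooth=True)
    step_h = step.total_seconds() / 3600.0
    lon_s, lat_s = planar_to_lonlat(msx[lattice_pos, 0], msy[lattice_pos, 0], lon_ref, lat_ref)
    sd_km = np.sqrt(0.5 * (np.abs(Psx[lattice_pos, 0, 0]) + np.abs(Psy[lattice_pos, 0, 0])))
    fit = CRWFit(gamma=float(math.exp(-theta * step_h)), sigma_km=sigma, converged=converged, n_obs=len(segment))
    if not converged:
        warnings.warn("CRW state-space fit did not converge; segment flagged", stacklevel=2)
    out = pd.DataFrame(
        {
            "individual_id": segment["individual_id"].iloc[0],
            "segment_id": segment["segment_id"].iloc[0] if "segment_id" in segment.columns else "0",
            "timestamp": lattice,
            "lon": lon_s,
            "lat": lat_s,
            "sd_km": sd_km,
        }
    )
    return out, fit


def regularize_tracks(track: pd.DataFrame, step=pd.Timedelta(hours=6), noise=None, min_fixes: int = 4) -> pd.DataFrame:
    """Apply :func:`fit_crw_ssm` per segment, skipping (with a warning)
    segments too short to regularize or failing to converge."""
    parts = []
    for seg_id, g in track.groupby("segment_id", sort=False):
        try:
            reg, fit = fit_crw_ssm(g, step=step, noise=noise)
        except ValueError as e:
            log.warning("segment %s skipped: %s", seg_id, e)
            continue
        if not fit.converged:
            log.warning("segment %s excluded: CRW fit did not converge", seg_id)
            continue
        parts.append(reg)
    if not parts:
        return pd.DataFrame(columns=["individual_id", "segment_id", "timestamp", "lon", "lat", "sd_km"])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# haul-outs and trips


def detect_haulouts(
    segment: pd.DataFrame,
    stack,
    radius_km: float = 12.0,
    min_dry: pd.Timedelta = pd.Timedelta(hours=6),
) -> pd.DataFrame:
    """Maximal intervals of a regularized segment during which every
    position lies within ``radius_km`` of a land (coast) cell centre — and is
    flagged dry when a ``dry`` column exists — for at least ``min_dry``.

    Returns a DataFrame with start, end, and a haul-out id derived from the
    modal grid cell occupied during the interval.
    """
    from .synth import grid_of

    grid = grid_of(stack)
    land = stack["land"].values
    li, lj = np.nonzero(land)
    rows = []
    if len(li) == 0 or len(segment) == 0:
        return pd.DataFrame(columns=["individual_id", "haulout_id", "start", "end"])
    lon_land, lat_land = grid.cell_center(li, lj)
    lon_p = segment["lon"].to_numpy()
    lat_p = segment["lat"].to_numpy()
    near = np.empty(len(segment), dtype=bool)
    for i in range(len(segment)):
        d = haversine_km(lon_p[i], lat_p[i], lon_land, lat_land)
        near[i] = d.min() <= radius_km
    if "dry" in segment.columns:
        near &= segment["dry"].to_numpy().astype(bool)
    ts = segment["timestamp"].reset_index(drop=True)
    iid = segment["individual_id"].iloc[0]
    i = 0
    while i < len(segment):
        if not near[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(segment) and near[j + 1]:
            j += 1
        if ts[j] - ts[i] >= min_dry:
            r, c = grid.to_cell(np.median(lon_p[i : j + 1]), np.median(lat_p[i : j + 1]))
            rows.append((iid, f"cell_{int(r)}_{int(c)}", ts[i], ts[j]))
        i = j + 1
    return pd.DataFrame(rows, columns=["individual_id", "haulout_id", "start", "end"])


def segment_trips(segment: pd.DataFrame, haulouts: pd.DataFrame) -> pd.DataFrame:
    """One trip per inter-haul-out gap containing at least one at-sea
    position.  ``round_trip`` is true iff the departure and arrival haul-out
    identities match (and the arrival exists)."""
    h = haulouts.sort_values("start").reset_index(drop=True)
    iid = segment["individual_id"].iloc[0] if len(segment) else None
    ts = segment["timestamp"]
    trips = []
    for k in range(len(h)):
        dep_t = h.loc[k, "end"]
        dep_id = h.loc[k, "haulout_id"]
        if k + 1 < len(h):
            arr_t = h.loc[k + 1, "start"]
            arr_id = h.loc[k + 1, "haulout_id"]
        else:
            arr_t = ts.iloc[-1] if len(ts) else None
            arr_id = None
        if arr_t is None or arr_t <= dep_t:
            continue
        at_sea = ((ts > dep_t) & (ts < arr_t)).sum()
        if at_sea < 1:
            continue
        trips.append(
            {
                "individual_id": iid,
                "departure": dep_t,
                "arrival": arr_t,
                "departure_haulout": dep_id,
                "arrival_haulout": arr_id,
                "duration_days": (arr_t - dep_t).total_seconds() / 86400.0,
                "round_trip": bool(arr_id is not None and arr_id == dep_id),
            }
        )
    return pd.DataFrame(
        trips,
        columns=[
            "individual_id",
            "departure",
            "arrival",
            "departure_haulout",
            "arrival_haulout",
            "duration_days",
            "round_trip",
        ],
    )
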