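"""End-to-end experiments on the synthetic study system.

Two study-scale experiments are provided: a full pipeline *recovery
experiment* — simulate a world with a known habitat preference, run
filtering, regularization, pseudo-absence construction, covariate matching,
model tuning, bootstrap prediction and accessibility weighting, and measure
how well the known truth is recovered — and a *state-space benefit
experiment* quantifying how much the CRW smoother reduces positional error
relative to the raw Argos fixes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import access, brt, envstack, preprocess, pseudoabs, synth
from .synth import ArgosNoiseSpec, SyntheticWorldConfig, TruthModel, grid_of

log = logging.getLogger(__name__)


def preprocess_tracks(obs: pd.DataFrame, noise: ArgosNoiseSpec, step=pd.Timedelta(hours=6)) -> pd.DataFrame:
    """Standard cleaning chain: near-duplicates, SDA filter, gap split,
    per-segment CRW regularization."""
    t = preprocess.remove_near_duplicates(obs)
    t = preprocess.sda_filter(t)
    t = preprocess.split_on_gaps(t)
    return preprocess.regularize_tracks(t, step=step, noise=noise)


def split_at_sea_runs(segment: pd.DataFrame, stack, radius_km: float = 12.0) -> list[pd.DataFrame]:
    """Contiguous at-sea runs of a regularized segment (haul-out residency
    removed).  The habitat model sees only at-sea behaviour; haul-out
    positions would otherwise flood the presence set with coastal cells."""
    h = preprocess.detect_haulouts(segment, stack, radius_km=radius_km)
    ts = segment["timestamp"]
    hauled = np.zeros(len(segment), dtype=bool)
    for _, hv in h.iterrows():
        hauled |= ((ts >= hv["start"]) & (ts <= hv["end"])).to_numpy()
    runs = []
    run_id = np.cumsum(hauled.astype(int))  # constant within an at-sea run
    at_sea = segment[~hauled]
    if len(at_sea) == 0:
        return []
    for _, g in at_sea.groupby(run_id[~hauled], sort=True):
        runs.append(g.reset_index(drop=True))
    return runs


def build_pa_table(
    reg: pd.DataFrame,
    stack,
    n_sim: int = 50,
    window_days: int = 2,
    seed: int = 0,
    min_steps: int = 10,
):
    """Pseudo-absence construction for all regularized segments.

    Per segment: the VAR movement model is fitted to the longest at-sea run,
    then ``n_sim`` null tracks are simulated for every at-sea run (trip),
    anchored at the trip's first location.  Presences are the at-sea
    positions.  Returns (balanced PA skeleton, at-sea presences, simulated
    tracks).
    """
    grid = grid_of(stack)
    land = stack["land"].values
    sims = []
    presence_parts = []
    k = 0
    for seg_id, g in reg.groupby("segment_id", sort=False):
        runs = split_at_sea_runs(g, stack)
        runs = [r for r in runs if len(r) >= 2]
        if not runs:
            continue
        presence_parts.extend(runs)
        longest = max(runs, key=len)
        if len(longest) < min_steps + 2:
            log.warning("segment %s: longest at-sea run too short for the movement model; skipped", seg_id)
            continue
        model = pseudoabs.fit_movement_model(longest)
        for r in runs:
            if len(r) < 3:
                continue
            k += 1
            try:
                sims.extend(
                    pseudoabs.simulate_pseudo_tracks(model, r, n=n_sim, grid=grid, land=land, seed=seed + 7919 * k)
                )
            except (RuntimeError, ValueError) as e:
                log.warning("segment %s trip %d: %s", seg_id, k, e)
    presences = pd.concat(presence_parts, ignore_index=True) if presence_parts else reg.iloc[0:0]
    gridded = pseudoabs.grid_locations(presences, sims, grid)
    gridded = pseudoabs.filter_contradictions(gridded, window_days=window_days)
    skeleton = pseudoabs.sample_balanced(gridded, grid, seed=seed + 13)
    return skeleton, presences, sims


DEFAULT_REDUCED_GRID = brt.BRTGrid(
    tree_counts=tuple(range(50, 1501, 50)),
    tree_complexity=(1, 3, 5),
    learning_rate=(0.05, 0.01),
    bag_fraction=(0.5,),
)


def run_recovery_experiment(
    seed: int = 1,
    n_individuals: int = 8,
    n_days: int = 120,
    nlat: int = 60,
    nlon: int = 60,
    n_sim: int = 10,
    n_boot: int = 20,
    beta: float = 15.0,
    truth_covariates: dict | None = None,
    grid: brt.BRTGrid | None = None,
    map_date_step: int = 7,
    noise_scale: float = 0.3,
    truth_kwargs: dict | None = None,
    world_kwargs: dict | None = None,
) -> dict:
    """Simulate, run the full pipeline, and score truth recovery.

    Returns a dict with the tuned configuration, cross-validated AUC,
    deviance explained, relative influences, the Spearman correlation of
    predicted vs true suitability on held-out cells, accessibility-curve
    monotonicity and the ice-exclusion check.
    """
    rng = np.random.default_rng(seed)
    truth_covariates = truth_covariates or {"sst": 2.0, "bat": -2.0, "sal": -2.0}
    config = SyntheticWorldConfig(
        seed=int(rng.integers(2**31 - 1)), n_days=n_days, nlat=nlat, nlon=nlon, **(world_kwargs or {})
    )
    stack = synth.generate_env_stack(config)
    stack = envstack.add_derived_layers(stack)
    truth = TruthModel(coefficients=truth_covariates, beta=beta, **(truth_kwargs or {}))
    noise = ArgosNoiseSpec().scaled(noise_scale)
    obs, true_paths, _ = synth.generate_tracks(
        stack, truth, n_individuals, noise=noise, seed=int(rng.integers(2**31 - 1)),
        duration_range_days=(max(n_days // 2, 26), n_days),
    )
    reg = preprocess_tracks(obs, noise)
    skeleton, presences, sims = build_pa_table(reg, stack, n_sim=n_sim, seed=int(rng.integers(2**31 - 1)))
    table = envstack.match_covariates(skeleton, stack)
    screen = envstack.collinearity_screen(table)
    kept = screen["kept"]
    table = brt.importance_control(table, seed=int(rng.integers(2**31 - 1)))
    model_covs = kept + [brt.RANDOM_CONTROL]

    sel_config, cv, scan = brt.tune_brt(
        table, model_covs, grid=grid or DEFAULT_REDUCED_GRID, seed=int(rng.integers(2**31 - 1))
    )
    final = brt.fit_brt(table, model_covs, sel_config, seed=int(rng.integers(2**31 - 1)))
    influence = brt.relative_influence(final)

    fits = brt.bootstrap_ensemble(table, model_covs, sel_config, n=n_boot, seed=int(rng.integers(2**31 - 1)))

    # predicted vs true suitability: monthly means of the daily bootstrap-
    # median maps (the pipeline's headline product), compared with the
    # matching monthly means of the true suitability, on held-out cells
    # (never used in training) within the model's applicability domain —
    # open water (SIC <= 0.15 on every averaged day; ice-covered cells are
    # the accessibility model's business, not the habitat model's) — pooled
    # over months
    dates = pd.DatetimeIndex(stack.time.values)
    map_dates = dates[::map_date_step]
    maps = brt.predict_maps(fits, stack, map_dates)
    suit_true = truth.suitability(stack)
    g = grid_of(stack)
    used_cells = set(zip(table["row"], table["col"]))
    held = np.ones((g.nlat, g.nlon), dtype=bool)
    for i, j in used_cells:
        held[i, j] = False
    # restrict to the sampled envelope: cells visited by any real or
    # simulated location — where the use-availability design has support
    envelope = np.zeros((g.nlat, g.nlon), dtype=bool)
    for df in [presences] + sims:
        if len(df) == 0:
            continue
        rr, cc = g.to_cell(df["lon"].to_numpy(), df["lat"].to_numpy())
        ok = rr >= 0
        envelope[rr[ok], cc[ok]] = True
    held &= envelope
    truth_monthly = suit_true.sel(time=map_dates).groupby("time.month").mean(skipna=True)
    sic_sel = stack["sic"].sel(time=map_dates)
    open_water_monthly = (sic_sel <= 0.15).groupby("time.month").all()
    pred_vals, true_vals = [], []
    for month in maps["monthly_median"].month.values:
        pm = maps["monthly_median"].sel(month=month).values
        tv = truth_monthly.sel(month=month).values
        ow = open_water_monthly.sel(month=month).values
        ok = held & ow & np.isfinite(pm) & np.isfinite(tv)
        pred_vals.append(pm[ok])
        true_vals.append(tv[ok])
    rho_truth = float(spearmanr(np.concatenate(pred_vals), np.concatenate(true_vals)).statistic)

    # accessibility on distance beyond the ice edge
    atab = access.build_access_table(reg, sims, stack)
    curve = access.fit_accessibility(atab, seed=int(rng.integers(2**31 - 1)), n_boot=n_boot)
    dgrid = np.arange(0.0, max(curve.support[1], 1.0) + 1.0, 1.0)
    fam = curve.family(dgrid)
    monotone_all = bool(np.all(np.diff(fam, axis=1) <= 1e-9))

    weighted = access.weight_predictions(maps, curve, stack)
    ice_zero_ok = True
    for d in map_dates:
        t = dates.get_loc(d)
        sic = stack["sic"].values[t]
        wmap = weighted["weighted_suitability"].sel(time=d).values
        mask = np.isfinite(wmap) & (sic > 0.15)
        if mask.any() and np.nanmax(np.abs(wmap[mask])) > 0:
            ice_zero_ok = False

    rand_infl = influence.get(brt.RANDOM_CONTROL, 0.0)
    truth_above_random = {c: bool(influence.get(c, 0.0) > rand_infl) for c in truth_covariates}

    return {
        "config": sel_config,
        "cv_auc": float(cv.mean_auc),
        "deviance_explained_pct": float(cv.deviance_explained),
        "influence": influence,
        "random_control_influence": float(rand_infl),
        "truth_above_random": truth_above_random,
        "spearman_pred_vs_truth": rho_truth,
        "accessibility_monotone": monotone_all,
        "ice_exclusion_ok": ice_zero_ok,
        "n_rows": int(len(table)),
        "n_individuals": int(table["individual_id"].nunique()),
        "screen_dropped": screen["dropped"],
    }


def run_ssm_benefit_experiment(seed: int = 1, n_tracks: int = 20, n_days: int = 12) -> dict:
    """Smoothed vs raw positional RMSE on simulated noisy tracks.

    For each replicate, one seal is simulated, observed with Argos noise,
    cleaned and regularized; RMSE of the smoothed 6-h positions against the
    true path (interpolated to the same times) is compared with the RMSE of
    the raw observations (class Z excluded — those fixes are flagged
    invalid, not mislocated).
    """
    from .geo import haversine_km

    rng = np.random.default_rng(seed)
    config = SyntheticWorldConfig(seed=int(rng.integers(2**31 - 1)), n_days=max(n_days + 4, 8), nlat=40, nlon=40)
    stack = synth.generate_env_stack(config)
    # moderately directed unbiased walk (mean 16 km per 6 h, persistent
    # headings): the regime where regularization is meant to operate
    truth = TruthModel(
        beta=0.0, p_depart_per_evening_hour=1.0, trip_days_start=n_days, trip_days_end=n_days,
        trip_sigma=0.01, step_scale_km=8.0, turn_kappa=0.8,
    )
    noise = ArgosNoiseSpec()
    improved = 0
    rmse_pairs = []
    k = 0
    while len(rmse_pairs) < n_tracks and k < 3 * n_tracks:
        k += 1
        obs, true_paths, _ = synth.generate_tracks(
            stack, truth, 1, noise=noise, seed=int(rng.integers(2**31 - 1)), duration_range_days=(n_days, n_days),
            obs_interval_mean_h=1.2,  # polar Argos coverage: ~20 fixes/day
        )
        t = preprocess.remove_near_duplicates(obs)
        t = preprocess.sda_filter(t)
        t = preprocess.split_on_gaps(t)
        seg = t[t["segment_id"] == t["segment_id"].iloc[0]]
        try:
            reg, fit = preprocess.fit_crw_ssm(seg, noise=noise)
        except ValueError:
            continue
        tp = true_paths.sort_values("timestamp")
        tt = tp["timestamp"].astype("int64").to_numpy() / 1e9

        def rmse(frame):
            ts = frame["timestamp"].astype("int64").to_numpy() / 1e9
            lon_t = np.interp(ts, tt, tp["lon"].to_numpy())
            lat_t = np.interp(ts, tt, tp["lat"].to_numpy())
            d = haversine_km(frame["lon"].to_numpy(), frame["lat"].to_numpy(), lon_t, lat_t)
            return float(np.sqrt(np.mean(d**2)))

        r_smooth = rmse(reg)
        r_raw = rmse(obs[obs["location_class"] != "Z"])
        rmse_pairs.append((r_smooth, r_raw))
        if r_smooth < r_raw:
            improved += 1
    return {
        "n": len(rmse_pairs),
        "n_improved": improved,
        "rmse_smoothed_km": float(np.mean([a for a, _ in rmse_pairs])),
        "rmse_raw_km": float(np.mean([b for _, b in rmse_pairs])),
    }
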