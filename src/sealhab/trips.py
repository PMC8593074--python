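"""Descriptive foraging-trip, dive and haul-out demography statistics.

Covers the field summaries surrounding the habitat model: per-individual
trip durations, departure/arrival timing in local solar hours, daylength
and its correlation with trip duration, daily maximum dive depth
aggregates, and the juvenile / sub-adult / adult composition of haul-out
transect censuses.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


def trip_durations(trips: pd.DataFrame) -> pd.DataFrame:
    """Per-individual trip count, mean duration and range (days), plus a
    pooled "(all)" row."""
    rows = []
    for iid, g in trips.groupby("individual_id", sort=True):
        d = g["duration_days"]
        rows.append((iid, len(g), d.mean(), d.min(), d.max()))
    d = trips["duration_days"]
    rows.append(("(all)", len(trips), d.mean() if len(d) else np.nan, d.min() if len(d) else np.nan, d.max() if len(d) else np.nan))
    return pd.DataFrame(rows, columns=["individual_id", "n_trips", "mean_days", "min_days", "max_days"])


def _local_solar_hour(ts: pd.Series, lon: pd.Series) -> np.ndarray:
    """Local solar time = UTC + longitude/15 h."""
    utc_h = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    return (utc_h.to_numpy() + np.asarray(lon, float) / 15.0) % 24.0


def departure_arrival_histogram(trips: pd.DataFrame, positions: pd.DataFrame, bin_hours: int = 1) -> pd.DataFrame:
    """Counts of departures and arrivals per local solar hour bin.

    Position longitudes are looked up from the regularized track at the
    departure/arrival times (nearest position of the same individual).
    """
    edges = np.arange(0, 24 + bin_hours, bin_hours)
    counts = {"hour": edges[:-1].astype(float)}
    for kind, col in (("departure", "departure"), ("arrival", "arrival")):
        lons = []
        tss = []
        for _, tr in trips.iterrows():
            t = tr[col]
            if pd.isna(t):
                continue
            g = positions[positions["individual_id"] == tr["individual_id"]]
            if len(g) == 0:
                continue
            i = (g["timestamp"] - t).abs().idxmin()
            lons.append(g.loc[i, "lon"])
            tss.append(t)
        if tss:
            hours = _local_solar_hour(pd.Series(tss), pd.Series(lons))
        else:
            hours = np.array([])
        counts[kind], _ = np.histogram(hours, bins=edges)
    return pd.DataFrame(counts)


def daylength(lat_deg: float, date) -> float:
    """Hours of daylight from the sunrise equation.

    Solar declination from the Spencer harmonic series (good to ~0.01 rad),
    polar day/night clamp to 24/0 h.
    """
    if abs(lat_deg) > 90:
        raise ValueError("latitude out of range")
    doy = pd.Timestamp(date).dayofyear
    g = 2.0 * np.pi / 365.0 * (doy - 1)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    phi = np.radians(lat_deg)
    cos_h0 = -np.tan(phi) * np.tan(decl)
    if cos_h0 >= 1.0:
        return 0.0
    if cos_h0 <= -1.0:
        return 24.0
    return float(2.0 * np.degrees(np.arccos(cos_h0)) / 15.0)


def correlate_daylength(trips: pd.DataFrame, positions: pd.DataFrame, at: str = "midpoint"):
    """Pearson correlation between per-trip daylength and trip duration.

    Daylength is evaluated at the trip's midpoint date and the individual's
    mean position over the trip (``at="departure"`` uses the departure date
    instead).  Returns (r, p, n); r is undefined (nan) under zero variance.
    """
    if len(trips) < 3:
        raise ValueError("need >= 3 trips")
    dl = []
    for _, tr in trips.iterrows():
        when = tr["departure"] if at == "departure" else tr["departure"] + (tr["arrival"] - tr["departure"]) / 2
        g = positions[
            (positions["individual_id"] == tr["individual_id"])
            & (positions["timestamp"] >= tr["departure"])
            & (positions["timestamp"] <= tr["arrival"])
        ]
        lat = g["lat"].mean() if len(g) else positions["lat"].mean()
        dl.append(daylength(lat, when))
    dur = trips["duration_days"].to_numpy(float)
    dl = np.asarray(dl)
    if np.std(dur) == 0 or np.std(dl) == 0:
        return float("nan"), float("nan"), len(trips)
    r, p = pearsonr(dl, dur)
    return float(r), float(p), len(trips)


def daily_max_depth(dives: pd.DataFrame) -> dict:
    """Per seal-day maximum depth and monthly mean +/- SD across seal-days.

    Days without dives are absent (not zero); negative depths are rejected.
    """
    if (dives["depth_m"] < 0).any():
        raise ValueError("negative dive depth")
    d = dives.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.normalize()
    daily = d.groupby(["individual_id", "date"], as_index=False)["depth_m"].max()
    daily = daily.rename(columns={"depth_m": "max_depth_m"})
    daily["month"] = daily["date"].dt.month
    monthly = daily.groupby("month")["max_depth_m"].agg(["mean", "std", "count"]).reset_index()
    return {
        "daily": daily,
        "monthly": monthly,
        "deepest_m": float(daily["max_depth_m"].max()) if len(daily) else float("nan"),
    }


def demography_summary(table: pd.DataFrame) -> dict:
    """Haul-out totals, pooled total, and per-class percentages with the
    across-census SD of the percentage."""
    if (table[["juveniles", "subadults", "adults"]] < 0).to_numpy().any():
        raise ValueError("negative counts")
    per_haulout = table.groupby("haulout")[["juveniles", "subadults", "adults"]].sum()
    per_haulout["total"] = per_haulout.sum(axis=1)
    pooled_total = int(per_haulout["total"].sum())
    per_census = table.groupby(["haulout", "census"])[["juveniles", "subadults", "adults"]].sum()
    tot = per_census.sum(axis=1)
    pct = per_census.div(tot, axis=0) * 100.0
    pct = pct[tot > 0]
    if pooled_total == 0:
        classes = {c: {"pct_mean": float("nan"), "pct_sd": float("nan")} for c in ("juveniles", "subadults", "adults")}
    else:
        classes = {
            c: {"pct_mean": float(pct[c].mean()), "pct_sd": float(pct[c].std(ddof=1)) if len(pct) > 1 else 0.0}
            for c in ("juveniles", "subadults", "adults")
        }
    return {"per_haulout": per_haulout, "pooled_total": pooled_total, "classes": classes}
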