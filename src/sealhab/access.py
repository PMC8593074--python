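"""Accessibility as a monotone non-increasing function of distance beyond
the ice edge.

Every open-water cell of the study grid gets a binary response — 1 if any
observed or simulated location ever fell in it, 0 otherwise — and its
distance beyond the 15% ice edge.  Accessibility is a binomial regression
of that response on distance under a monotone non-increasing shape
constraint: logistic regression on an I-spline (integrated B-spline) basis
with sign-constrained coefficients and a light second-difference smoothness
penalty.  Uncertainty comes from 50 half-data bootstrap refits; the point
curve is their pointwise median.  Habitat-suitability maps are weighted by
accessibility, with sea-ice concentration > 15% forced inaccessible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .geo import GridSpec
from .synth import grid_of

log = logging.getLogger(__name__)


def build_access_table(
    real_tracks: pd.DataFrame,
    simulated_tracks: list[pd.DataFrame],
    stack: xr.Dataset,
    pooled: bool = True,
) -> pd.DataFrame:
    """Binary accessibility response per open-water cell.

    A cell is accessible (1) if any observed or simulated location ever fell
    in it.  The distance covariate is the cell's mean distance beyond the
    ice edge over the stack's days (``pooled=True``) so each cell enters
    once; per-day evaluation is used at weighting time.
    """
    grid = grid_of(stack)
    land = stack["land"].values
    visited = np.zeros(land.shape, dtype=bool)
    for df in [real_tracks] + list(simulated_tracks):
        if len(df) == 0:
            continue
        r, c = grid.to_cell(df["lon"].to_numpy(), df["lat"].to_numpy())
        ok = r >= 0
        visited[r[ok], c[ok]] = True
    edge = stack["edge"].values  # (time, lat, lon)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        edge_mean = np.nanmean(edge, axis=0) if pooled else edge[0]
    sea_i, sea_j = np.nonzero(~land)
    d = edge_mean[sea_i, sea_j]
    resp = visited[sea_i, sea_j].astype(int)
    tab = pd.DataFrame({"row": sea_i, "col": sea_j, "response": resp, "distance_km": d})
    return tab[np.isfinite(tab["distance_km"])].reset_index(drop=True)


def _ispline_basis(x: np.ndarray, knots: np.ndarray, degree: int = 2) -> np.ndarray:
    """I-spline design matrix: monotone non-decreasing basis in [0, 1].

    Built as reversed cumulative sums of a clamped B-spline basis of the
    given degree; columns are non-decreasing in x, 0 at the left boundary
    and 1 at the right.
    """
    t = np.concatenate([[knots[0]] * (degree + 1), knots[1:-1], [knots[-1]] * (degree + 1)])
    xc = np.clip(x, knots[0], knots[-1])
    B = BSpline.design_matrix(xc, t, degree).toarray()
    I = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return I[:, 1:]  # drop the constant (all-ones) leading column


@dataclass
class AccessibilityCurve:
    """Monotone non-increasing access probability vs distance beyond the
    ice edge, with its bootstrap family."""

    knots: np.ndarray
    degree: int
    intercepts: np.ndarray  # (n_boot,)
    coefs: np.ndarray  # (n_boot, n_basis), all >= 0
    support: tuple

    def _eval_one(self, d: np.ndarray, b: int) -> np.ndarray:
        I = _ispline_basis(np.asarray(d, float), self.knots, self.degree)
        eta = self.intercepts[b] - I @ self.coefs[b]
        return 1.0 / (1.0 + np.exp(-eta))

    def family(self, d: np.ndarray) -> np.ndarray:
        """(n_boot, len(d)) access probabilities for every bootstrap fit."""
        d = np.asarray(d, float)
        return np.stack([self._eval_one(d, b) for b in range(len(self.intercepts))])

    def __call__(self, d: np.ndarray) -> np.ndarray:
        """Point curve: pointwise median of the bootstrap family."""
        return np.median(self.family(d), axis=0)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "knots": self.knots.tolist(),
                "degree": self.degree,
                "intercepts": self.intercepts.tolist(),
                "coefs": self.coefs.tolist(),
                "support": list(self.support),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "AccessibilityCurve":
        import json

        d = json.loads(payload)
        return cls(
            knots=np.asarray(d["knots"]),
            degree=int(d["degree"]),
            intercepts=np.asarray(d["intercepts"]),
            coefs=np.asarray(d["coefs"]),
            support=tuple(d["support"]),
        )


def _fit_monotone_logistic(d, y, knots, degree, penalty):
    I = _ispline_basis(d, knots, degree)
    k = I.shape[1]

    def negll(params):
        a, c = params[0], params[1:]
        eta = a - I @ c
        # stable log-likelihood
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        pen = penalty * np.sum(np.diff(c, 2) ** 2) if k > 2 else 0.0
        return -ll + pen

    def grad(params):
        a, c = params[0], params[1:]
        eta = a - I @ c
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -60, 60)))
        resid = y - p
        g = np.empty(k + 1)
        g[0] = -np.sum(resid)
        g[1:] = I.T @ resid
        if k > 2:
            D2 = np.diff(np.eye(k), 2, axis=0)
            g[1:] += 2.0 * penalty * (D2.T @ (D2 @ c))
        return g

    p0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    x0 = np.concatenate([[np.log(p0 / (1 - p0))], np.full(k, 0.01)])
    bounds = [(None, None)] + [(0.0, None)] * k
    res = minimize(negll, x0, jac=grad, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500})
    return float(res.x[0]), np.maximum(res.x[1:], 0.0)


def fit_single(
    table: pd.DataFrame,
    n_knots: int = 8,
    degree: int = 2,
    penalty: float = 1.0,
) -> AccessibilityCurve:
    """One monotone non-increasing binomial fit on the full table (no
    bootstrap); with ``penalty=0`` and a dense knot set this approaches the
    isotonic (pool-adjacent-violators) solution."""
    d = table["distance_km"].to_numpy(float)
    y = table["response"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("accessibility fit needs both classes")
    qs = np.linspace(0, 1, n_knots)
    knots = np.unique(np.quantile(d, qs))
    if len(knots) < 3:
        knots = np.linspace(d.min(), d.max() + 1e-6, 3)
    a, c = _fit_monotone_logistic(d, y, knots, degree, penalty)
    return AccessibilityCurve(
        knots=knots, degree=degree, intercepts=np.array([a]), coefs=c[None, :], support=(float(d.min()), float(d.max()))
    )


def fit_accessibility(
    table: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 50,
    n_knots: int = 8,
    degree: int = 2,
    penalty: float = 1.0,
) -> AccessibilityCurve:
    """Bootstrap family of monotone non-increasing binomial fits.

    Each of the ``n_boot`` fits uses a half-size resample drawn with
    replacement.  ``penalty`` is the second-difference smoothness weight
    (0 disables smoothing, approaching the isotonic-regression solution as
    the knot set grows dense).
    """
    d = table["distance_km"].to_numpy(float)
    y = table["response"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("accessibility fit needs both accessible and non-accessible cells")
    qs = np.linspace(0, 1, n_knots)
    knots = np.unique(np.quantile(d, qs))
    if len(knots) < 3:
        knots = np.linspace(d.min(), d.max() + 1e-6, 3)
    rng = np.random.default_rng(seed)
    N = len(d)
    half = max(N // 2, 10)
    intercepts = np.empty(n_boot)
    coefs = []
    b = 0
    while b < n_boot:
        idx = rng.choice(N, size=min(half, N), replace=True)
        if y[idx].min() == y[idx].max():
            continue
        a, c = _fit_monotone_logistic(d[idx], y[idx], knots, degree, penalty)
        intercepts[b] = a
        coefs.append(c)
        b += 1
    return AccessibilityCurve(
        knots=knots,
        degree=degree,
        intercepts=intercepts,
        coefs=np.stack(coefs),
        support=(float(d.min()), float(d.max())),
    )


def weight_predictions(
    habitat: xr.Dataset,
    curve: AccessibilityCurve,
    stack: xr.Dataset,
    sic_threshold: float = 0.15,
) -> xr.Dataset:
    """Weight daily habitat-suitability maps by accessibility.

    weighted = suitability x access(distance beyond edge); cells with SIC >
    15% are forced to 0; land stays missing.  Uses each day's own EDGE and
    SIC layers.
    """
    hab_dates = pd.DatetimeIndex(habitat.time.values)
    stack_dates = pd.DatetimeIndex(stack.time.values)
    if len(hab_dates.difference(stack_dates)):
        raise ValueError("habitat dates not covered by the environmental stack")
    land = stack["land"].values
    out = np.full(habitat["suitability_median"].shape, np.nan)
    for i, date in enumerate(hab_dates):
        t = stack_dates.get_loc(date)
        suit = habitat["suitability_median"].values[i]
        edge = stack["edge"].values[t]
        sic = stack["sic"].values[t]
        w = np.full(edge.shape, np.nan)
        fin = np.isfinite(edge)
        w[fin] = curve(edge[fin])
        weighted = suit * w
        weighted[np.isfinite(sic) & (sic > sic_threshold)] = 0.0
        weighted[land] = np.nan
        out[i] = weighted
    ds = xr.Dataset(
        {"weighted_suitability": (("time", "lat", "lon"), out)},
        coords={"time": habitat.time, "lat": habitat.lat, "lon": habitat.lon},
    )
    ds["monthly_weighted"] = ds["weighted_suitability"].groupby("time.month").mean(skipna=True)
    return ds
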