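"""Boosted regression trees for presence/pseudo-absence habitat modelling.

Stagewise gradient boosting of the Bernoulli deviance: at each iteration a
best-first regression tree with a fixed number of splits ("tree
complexity") is fitted to the current gradient residuals on a random
``bag_fraction`` subsample, its terminal-node values are one-step Newton
estimates, and the tree is shrunk by the learning rate and added to the
ensemble on the logit scale.  Missing covariate values are routed to the
majority child at each split.

Model selection follows the telemetry-SDM recipe: a grid over tree
complexity, learning rate and bag fraction, scanning the number of trees in
50-tree increments, scored by leave-one-individual-out cross-validated AUC
(all of a seal's rows — its presences and the pseudo-absences simulated
from its tracks — are held out together).  Uncertainty comes from refitting
the selected model on half-size bootstrap resamples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from numba import njit
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

RANDOM_CONTROL = "random_ctrl"


@dataclass(frozen=True)
class BRTConfig:
    """One hyperparameter combination."""

    n_trees: int
    tree_complexity: int
    learning_rate: float
    bag_fraction: float


#: the configuration selected in the 2019 winter fur-seal tracking study
WINTER2019 = BRTConfig(n_trees=1050, tree_complexity=5, learning_rate=0.01, bag_fraction=0.5)


@dataclass(frozen=True)
class BRTGrid:
    """Candidate hyperparameter sets scanned during tuning."""

    tree_counts: tuple = tuple(range(50, 10001, 50))
    tree_complexity: tuple = (1, 3, 5)
    learning_rate: tuple = (0.005, 0.001, 0.05, 0.01)
    bag_fraction: tuple = (0.5, 0.6, 0.7)

    def combinations(self):
        return [
            (tc, lr, bf)
            for tc in self.tree_complexity
            for lr in self.learning_rate
            for bf in self.bag_fraction
        ]


@dataclass
class CVResult:
    fold_ids: list
    fold_auc: np.ndarray
    mean_auc: float
    deviance_explained: float


#: bin code marking a missing covariate value
_MISSING_BIN = np.uint16(65535)


def _make_bins(X: np.ndarray, max_bins: int = 255):
    """Quantile pre-binning of the training design matrix.

    Small features (few unique values) keep exact midpoints as cut points,
    so splits on them are exact; larger features use up to ``max_bins``
    quantile cuts.  Returns the binned uint16 matrix plus the flat cut array
    and per-feature offsets used to translate a bin split back into a
    real-valued threshold.
    """
    n, p = X.shape
    B = np.empty((n, p), dtype=np.uint16)
    cuts_list = []
    for j in range(p):
        v = X[:, j]
        fin = v[np.isfinite(v)]
        uniq = np.unique(fin)
        if len(uniq) <= 1:
            cuts = np.empty(0)
        elif len(uniq) <= max_bins:
            cuts = 0.5 * (uniq[:-1] + uniq[1:])
        else:
            cuts = np.unique(np.quantile(fin, np.linspace(0, 1, max_bins + 1)[1:-1]))
        cuts_list.append(cuts)
        codes = np.searchsorted(cuts, v, side="left")
        codes[~np.isfinite(v)] = int(_MISSING_BIN)
        B[:, j] = codes.astype(np.uint16)
    offsets = np.zeros(p + 1, dtype=np.int64)
    for j in range(p):
        offsets[j + 1] = offsets[j] + len(cuts_list[j])
    cuts_flat = np.concatenate(cuts_list) if offsets[-1] else np.empty(0)
    return np.ascontiguousarray(B), cuts_flat, offsets


@njit(cache=True)
def _best_split_hist(B, r, rows, offsets, min_leaf, hist_s, hist_c):
    """Best SSE-reduction split over all features for one node, on the
    pre-binned matrix.  Missing values go to the (finite-count) majority
    child.  Returns (feature, split bin, gain, nan_left)."""
    m = rows.size
    p = B.shape[1]
    best_gain = 0.0
    best_feat = -1
    best_bin = -1
    best_nan_left = False
    sum_all = 0.0
    for k in range(m):
        sum_all += r[rows[k]]
    parent = (sum_all * sum_all) / m
    for j in range(p):
        n_cuts = offsets[j + 1] - offsets[j]
        if n_cuts == 0:
            continue
        for b in range(n_cuts + 1):
            hist_s[b] = 0.0
            hist_c[b] = 0
        nan_sum = 0.0
        nan_cnt = 0
        for k in range(m):
            c = B[rows[k], j]
            if c == 65535:
                nan_sum += r[rows[k]]
                nan_cnt += 1
            else:
                hist_s[c] += r[rows[k]]
                hist_c[c] += 1
        m_fin = m - nan_cnt
        if m_fin < 2 * min_leaf:
            continue
        csum = 0.0
        ccnt = 0
        for b in range(n_cuts):
            csum += hist_s[b]
            ccnt += hist_c[b]
            nl = ccnt
            nr = m_fin - ccnt
            if nl < min_leaf or nr < min_leaf or nl == 0 or nr == 0:
                continue
            lsum = csum
            rsum = (sum_all - nan_sum) - csum
            nl_eff = nl
            nr_eff = nr
            to_left = nl >= nr
            if nan_cnt > 0:
                if to_left:
                    lsum += nan_sum
                    nl_eff += nan_cnt
                else:
                    rsum += nan_sum
                    nr_eff += nan_cnt
            gain = lsum * lsum / nl_eff + rsum * rsum / nr_eff - parent
            if gain > best_gain:
                best_gain = gain
                best_feat = j
                best_bin = b
                best_nan_left = to_left
    return best_feat, best_bin, best_gain, best_nan_left


@njit(cache=True)
def _build_tree(B, r, w, bag, n_splits, min_leaf, cuts_flat, offsets):
    """Best-first regression tree with at most n_splits splits on the
    pre-binned design.  Returns flat node arrays (with real-valued
    thresholds for prediction on raw covariates) plus the realized
    (feature, gain) of each split for relative-influence accounting."""
    max_nodes = 2 * n_splits + 1
    feat = np.full(max_nodes, -1, dtype=np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    nanleft = np.zeros(max_nodes, dtype=np.uint8)
    val = np.zeros(max_nodes)
    count = np.zeros(max_nodes, dtype=np.int64)
    split_feat = np.full(n_splits, -1, dtype=np.int64)
    split_gain = np.zeros(n_splits)

    max_cuts = 0
    for j in range(B.shape[1]):
        nc = offsets[j + 1] - offsets[j]
        if nc > max_cuts:
            max_cuts = nc
    hist_s = np.zeros(max_cuts + 1)
    hist_c = np.zeros(max_cuts + 1, dtype=np.int64)

    node_of = np.zeros(bag.size, dtype=np.int64)
    n_nodes = 1
    # lazy per-leaf best-split cache
    cached = np.zeros(max_nodes, dtype=np.uint8)
    cg = np.zeros(max_nodes)
    cf = np.full(max_nodes, -1, dtype=np.int64)
    cb = np.full(max_nodes, -1, dtype=np.int64)
    cn = np.zeros(max_nodes, dtype=np.uint8)

    for s in range(n_splits):
        for node in range(n_nodes):
            if feat[node] == -1 and cached[node] == 0:
                rows = bag[node_of == node]
                f, b, g, nl = _best_split_hist(B, r, rows, offsets, min_leaf, hist_s, hist_c)
                cf[node], cb[node], cg[node], cn[node] = f, b, g, 1 if nl else 0
                cached[node] = 1
        best_node = -1
        best_gain = 0.0
        for node in range(n_nodes):
            if feat[node] == -1 and cf[node] >= 0 and cg[node] > best_gain:
                best_gain = cg[node]
                best_node = node
        if best_node < 0:
            break
        j = cf[best_node]
        b = cb[best_node]
        nl = cn[best_node] == 1
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[best_node] = j
        thr[best_node] = cuts_flat[offsets[j] + b]
        left[best_node] = lid
        right[best_node] = rid
        nanleft[best_node] = 1 if nl else 0
        split_feat[s] = j
        split_gain[s] = best_gain
        for k in range(bag.size):
            if node_of[k] == best_node:
                c = B[bag[k], j]
                if c == 65535:
                    node_of[k] = lid if nl else rid
                else:
                    node_of[k] = lid if c <= b else rid
    # terminal-node Newton estimates
    sr = np.zeros(n_nodes)
    sw = np.zeros(n_nodes)
    for k in range(bag.size):
        node = node_of[k]
        sr[node] += r[bag[k]]
        sw[node] += w[bag[k]]
        count[node] += 1
    for node in range(n_nodes):
        if feat[node] == -1:
            v = sr[node] / (sw[node] + 1e-9)
            if v > 8.0:
                v = 8.0
            elif v < -8.0:
                v = -8.0
            val[node] = v
    return feat[:n_nodes], thr[:n_nodes], left[:n_nodes], right[:n_nodes], nanleft[:n_nodes], val[:n_nodes], count[:n_nodes], split_feat, split_gain


@njit(cache=True)
def _add_tree_prediction(X, feat, thr, left, right, nanleft, val, scale, out):
    for i in range(X.shape[0]):
        node = 0
        while feat[node] != -1:
            v = X[i, feat[node]]
            if np.isnan(v):
                node = left[node] if nanleft[node] == 1 else right[node]
            else:
                node = left[node] if v <= thr[node] else right[node]
        out[i] += scale * val[node]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class BRTFit:
    """Fitted boosted-tree ensemble on the logit scale."""

    def __init__(self, covariates, config: BRTConfig, f0: float, trees, gains: np.ndarray, X_train: np.ndarray):
        self.covariates = list(covariates)
        self.config = config
        self.f0 = f0
        self.trees = trees  # list of node-array tuples
        self._gains = gains  # per-covariate accumulated split gain
        self.X_train = X_train
        self.n_train = len(X_train)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def decision(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Ensemble logit F(x) using the first ``n_trees`` trees."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.full(X.shape[0], self.f0)
        use = self.n_trees if n_trees is None else min(n_trees, self.n_trees)
        lr = self.config.learning_rate
        for m in range(use):
            feat, thr, left, right, nanleft, val, _ = self.trees[m]
            _add_tree_prediction(X, feat, thr, left, right, nanleft, val, lr, out)
        return out

    def staged_decision(self, X: np.ndarray, checkpoints) -> dict[int, np.ndarray]:
        """Logit predictions at several tree counts in one pass."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.full(X.shape[0], self.f0)
        lr = self.config.learning_rate
        res = {}
        cps = sorted(c for c in checkpoints if c <= self.n_trees)
        nxt = 0
        for m in range(self.n_trees):
            feat, thr, left, right, nanleft, val, _ = self.trees[m]
            _add_tree_prediction(X, feat, thr, left, right, nanleft, val, lr, out)
            while nxt < len(cps) and m + 1 == cps[nxt]:
                res[cps[nxt]] = out.copy()
                nxt += 1
            if nxt >= len(cps):
                break
        return res

    def predict(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Probability predictions in (0, 1)."""
        return _sigmoid(self.decision(X, n_trees))

    def to_json(self) -> str:
        """Serialize the ensemble (trees as nested split records)."""
        import json

        trees = []
        for feat, thr, left, right, nanleft, val, count in self.trees:
            trees.append(
                {
                    "feature": feat.tolist(),
                    "threshold": thr.tolist(),
                    "left": left.tolist(),
                    "right": right.tolist(),
                    "nan_left": nanleft.tolist(),
                    "value": val.tolist(),
                    "count": count.tolist(),
                }
            )
        return json.dumps(
            {
                "covariates": self.covariates,
                "config": {
                    "n_trees": self.config.n_trees,
                    "tree_complexity": self.config.tree_complexity,
                    "learning_rate": self.config.learning_rate,
                    "bag_fraction": self.config.bag_fraction,
                },
                "f0": self.f0,
                "gains": self._gains.tolist(),
                "trees": trees,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "BRTFit":
        """Rebuild an ensemble serialized with :meth:`to_json`.

        The training matrix is not stored, so partial dependence is
        unavailable on a deserialized model; prediction is unaffected.
        """
        import json

        d = json.loads(payload)
        trees = [
            (
                np.asarray(t["feature"], dtype=np.int64),
                np.asarray(t["threshold"], dtype=float),
                np.asarray(t["left"], dtype=np.int64),
                np.asarray(t["right"], dtype=np.int64),
                np.asarray(t["nan_left"], dtype=np.uint8),
                np.asarray(t["value"], dtype=float),
                np.asarray(t["count"], dtype=np.int64),
            )
            for t in d["trees"]
        ]
        cfg = BRTConfig(**d["config"])
        return cls(d["covariates"], cfg, d["f0"], trees, np.asarray(d["gains"]), np.empty((0, len(d["covariates"]))))


def _design(table: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(covariates)].to_numpy(dtype=np.float64)
    y = table["response"].to_numpy(dtype=np.float64)
    return np.ascontiguousarray(X), y


def fit_brt(
    table: pd.DataFrame,
    covariates,
    config: BRTConfig,
    seed: int = 0,
    min_samples_leaf: int = 5,
    row_index: np.ndarray | None = None,
) -> BRTFit:
    """Fit the Bernoulli boosted-tree ensemble.

    ``row_index`` optionally restricts training to a subset (bootstrap or CV
    fold) without copying the table.  Deterministic under a fixed seed.
    """
    X, y = _design(table, covariates)
    if row_index is not None:
        X = np.ascontiguousarray(X[row_index])
        y = y[row_index]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("single-class response: cannot fit a Bernoulli model")
    rng = np.random.default_rng(seed)
    n = len(y)
    pbar = y.mean()
    f0 = float(np.log(pbar / (1.0 - pbar)))
    F = np.full(n, f0)
    n_bag = max(int(round(config.bag_fraction * n)), 2 * min_samples_leaf)
    trees = []
    gains = np.zeros(len(covariates))
    B, cuts_flat, offsets = _make_bins(X)
    for _ in range(config.n_trees):
        p = _sigmoid(F)
        r = y - p
        w = p * (1.0 - p)
        bag = rng.choice(n, size=min(n_bag, n), replace=False).astype(np.int64)
        feat, thr, left, right, nanleft, val, count, sfeat, sgain = _build_tree(
            B, r, w, bag, config.tree_complexity, min_samples_leaf, cuts_flat, offsets
        )
        for jf, jg in zip(sfeat, sgain):
            if jf >= 0:
                gains[jf] += jg
        tree = (feat, thr, left, right, nanleft, val, count)
        trees.append(tree)
        _add_tree_prediction(X, feat, thr, left, right, nanleft, val, config.learning_rate, F)
    return BRTFit(covariates, config, f0, trees, gains, X)


def importance_control(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Append the random-number control covariate (uniform integer 1-100).

    Covariates whose relative influence does not exceed the control's are
    flagged as uninformative in downstream reporting.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out[RANDOM_CONTROL] = rng.integers(1, 101, size=len(table)).astype(float)
    return out


def relative_influence(fit: BRTFit) -> pd.Series:
    """Per-covariate share (%) of the total split-gain reduction; sums to 100."""
    total = fit._gains.sum()
    if total <= 0:
        vals = np.zeros(len(fit.covariates))
    else:
        vals = 100.0 * fit._gains / total
    return pd.Series(vals, index=fit.covariates).sort_values(ascending=False)


def partial_dependence(fit: BRTFit, covariate: str, grid_values: np.ndarray) -> pd.DataFrame:
    """Model response vs one covariate with the others integrated out over
    the training distribution: for each grid value the covariate's column is
    substituted into every training row, the ensemble logit is averaged, and
    the average is inverse-logit transformed."""
    if covariate not in fit.covariates:
        raise ValueError(f"unknown covariate {covariate!r}")
    j = fit.covariates.index(covariate)
    logits = np.empty(len(grid_values))
    X = fit.X_train.copy()
    for i, v in enumerate(np.asarray(grid_values, dtype=float)):
        X[:, j] = v
        logits[i] = fit.decision(X).mean()
    return pd.DataFrame({covariate: grid_values, "logit": logits, "prob": _sigmoid(logits)})


def _fold_prevalence_logit(y):
    p = np.clip(y.mean(), 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def tune_brt(
    table: pd.DataFrame,
    covariates,
    grid: BRTGrid | None = None,
    seed: int = 0,
    min_trees: int = 1000,
    min_samples_leaf: int = 5,
) -> tuple[BRTConfig, CVResult, pd.DataFrame]:
    """Leave-one-individual-out hyperparameter search.

    For every (tree complexity, learning rate, bag fraction) combination the
    tree-count axis is scanned in one pass per fold via staged predictions;
    the selected combination MAXIMIZES mean cross-validated AUC subject to
    > ``min_trees`` trees, with ties broken toward larger learning rates,
    then smaller tree complexities, then fewer trees.  If no candidate
    reaches ``min_trees`` trees the constraint is relaxed with a warning.

    Returns (selected config, its CVResult, the full scan table).
    """
    grid = grid or BRTGrid()
    folds = list(pd.unique(table["individual_id"]))
    if len(folds) < 2:
        raise ValueError("need >= 2 individuals for leave-one-individual-out CV")
    max_trees = max(grid.tree_counts)
    checkpoints = sorted(grid.tree_counts)
    iid = table["individual_id"].to_numpy()
    y_all = table["response"].to_numpy(dtype=float)
    X_all, _ = _design(table, covariates)

    rows = []
    # per (combo, checkpoint): fold AUCs and pooled deviance components
    fold_stats: dict[tuple, dict] = {}
    for tc, lr, bf in grid.combinations():
        auc_by_cp = {cp: [] for cp in checkpoints}
        dev_by_cp = {cp: [0.0, 0.0] for cp in checkpoints}  # model, null
        for f_i, fold in enumerate(folds):
            test = iid == fold
            train_idx = np.nonzero(~test)[0]
            fit = fit_brt(
                table,
                covariates,
                BRTConfig(max_trees, tc, lr, bf),
                seed=seed + 1000 * f_i,
                min_samples_leaf=min_samples_leaf,
                row_index=train_idx,
            )
            staged = fit.staged_decision(X_all[test], checkpoints)
            yt = y_all[test]
            p0 = np.clip(_sigmoid(np.full(test.sum(), _fold_prevalence_logit(y_all[train_idx]))), 1e-9, 1 - 1e-9)
            d_null = float(-2.0 * np.sum(yt * np.log(p0) + (1 - yt) * np.log(1 - p0)))
            two_class = len(np.unique(yt)) >= 2
            for cp, F in staged.items():
                p = np.clip(_sigmoid(F), 1e-9, 1 - 1e-9)
                dev_by_cp[cp][0] += float(-2.0 * np.sum(yt * np.log(p) + (1 - yt) * np.log(1 - p)))
                dev_by_cp[cp][1] += d_null
                if two_class:
                    auc_by_cp[cp].append(roc_auc_score(yt, F))
        for cp in checkpoints:
            if auc_by_cp[cp]:
                rows.append((tc, lr, bf, cp, float(np.mean(auc_by_cp[cp]))))
                fold_stats[(tc, lr, bf, cp)] = {
                    "fold_auc": np.array(auc_by_cp[cp]),
                    "dev_model": dev_by_cp[cp][0],
                    "dev_null": dev_by_cp[cp][1],
                }
    scan = pd.DataFrame(rows, columns=["tree_complexity", "learning_rate", "bag_fraction", "n_trees", "cv_auc"])

    eligible = scan[scan["n_trees"] > min_trees]
    if eligible.empty:
        log.warning("no candidate reached > %d trees; relaxing the tree-count constraint", min_trees)
        eligible = scan
    best_auc = eligible["cv_auc"].max()
    ties = eligible[np.isclose(eligible["cv_auc"], best_auc, atol=1e-12)]
    ties = ties.sort_values(
        ["learning_rate", "tree_complexity", "n_trees"], ascending=[False, True, True], kind="stable"
    )
    sel = ties.iloc[0]
    config = BRTConfig(int(sel["n_trees"]), int(sel["tree_complexity"]), float(sel["learning_rate"]), float(sel["bag_fraction"]))

    stats = fold_stats[(config.tree_complexity, config.learning_rate, config.bag_fraction, config.n_trees)]
    cv = CVResult(
        fold_ids=folds,
        fold_auc=stats["fold_auc"],
        mean_auc=float(np.mean(stats["fold_auc"])),
        deviance_explained=float(100.0 * (1.0 - stats["dev_model"] / stats["dev_null"])),
    )
    return config, cv, scan


def bootstrap_ensemble(
    table: pd.DataFrame,
    covariates,
    config: BRTConfig,
    n: int = 50,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> list[BRTFit]:
    """Fit the model ``n`` times on half-size resamples drawn with
    replacement; single-class resamples are redrawn (logged)."""
    rng = np.random.default_rng(seed)
    N = len(table)
    half = N // 2
    y = table["response"].to_numpy()
    fits = []
    redraws = 0
    while len(fits) < n:
        idx = rng.choice(N, size=half, replace=True)
        if len(np.unique(y[idx])) < 2:
            redraws += 1
            continue
        fits.append(
            fit_brt(table, covariates, config, seed=int(rng.integers(2**31 - 1)), min_samples_leaf=min_samples_leaf, row_index=idx)
        )
    if redraws:
        log.info("redrew %d single-class bootstrap resamples", redraws)
    return fits


def predict_maps(
    fits: list[BRTFit],
    stack: xr.Dataset,
    dates,
    covariates=None,
    random_control_value: float = 50.5,
) -> xr.Dataset:
    """Daily median and 95% CI-range suitability maps from the bootstrap
    ensemble, plus monthly means of both.

    The random control covariate (if in the model) is held at its midpoint.
    Land cells and cells with missing required covariates are missing.
    """
    covariates = covariates or fits[0].covariates
    stack_dates = pd.DatetimeIndex(stack.time.values)
    dates = pd.DatetimeIndex(dates)
    missing_dates = dates.difference(stack_dates)
    if len(missing_dates):
        raise ValueError(f"dates outside the stack: {list(missing_dates)}")
    nlat = stack.sizes["lat"]
    nlon = stack.sizes["lon"]
    med = np.full((len(dates), nlat, nlon), np.nan)
    rng95 = np.full_like(med, np.nan)
    land = stack["land"].values
    sea = ~land
    sea_flat = np.nonzero(sea.ravel())[0]
    for d_i, date in enumerate(dates):
        t = stack_dates.get_loc(date)
        cols = []
        for c in covariates:
            if c == RANDOM_CONTROL:
                cols.append(np.full(len(sea_flat), random_control_value))
                continue
            layer = stack[c].values[t] if "time" in stack[c].dims else stack[c].values
            cols.append(layer.ravel()[sea_flat].astype(float))
        X = np.ascontiguousarray(np.column_stack(cols))
        preds = np.stack([f.predict(X) for f in fits])
        m = np.median(preds, axis=0)
        lo = np.quantile(preds, 0.025, axis=0)
        hi = np.quantile(preds, 0.975, axis=0)
        med_flat = np.full(nlat * nlon, np.nan)
        rng_flat = np.full(nlat * nlon, np.nan)
        med_flat[sea_flat] = m
        rng_flat[sea_flat] = hi - lo
        med[d_i] = med_flat.reshape(nlat, nlon)
        rng95[d_i] = rng_flat.reshape(nlat, nlon)
    ds = xr.Dataset(
        {
            "suitability_median": (("time", "lat", "lon"), med),
            "suitability_ci_range": (("time", "lat", "lon"), rng95),
        },
        coords={"time": dates, "lat": stack.lat, "lon": stack.lon},
        attrs=dict(stack.attrs),
    )
    monthly = ds.groupby("time.month").mean(skipna=True)
    ds["monthly_median"] = monthly["suitability_median"]
    ds["monthly_ci_range"] = monthly["suitability_ci_range"]
    return ds
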