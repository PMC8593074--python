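"""Boosted-tree ensemble: fitting, tuning, influence, PD, bootstrap, maps."""
import numpy as np
import pandas as pd
import pytest
import xarray as xr
from sklearn.metrics import roc_auc_score

from sealhab import brt
from sealhab.brt import (
    BRTConfig,
    BRTGrid,
    WINTER2019,
    RANDOM_CONTROL,
    bootstrap_ensemble,
    fit_brt,
    importance_control,
    partial_dependence,
    predict_maps,
    relative_influence,
    tune_brt,
)


@pytest.fixture(scope="module")
def toy_table():
    rng = np.random.default_rng(0)
    n = 600
    t = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "z": rng.normal(size=n),
            "w": rng.normal(size=n),
            "individual_id": rng.choice([f"i{k}" for k in range(4)], size=n),
        }
    )
    logit = 2.5 * t["x"] - 1.5 * t["z"]
    t["response"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    t["date"] = pd.Timestamp("2019-03-01")
    return t


COVS = ["x", "z", "w"]


class TestFitBrt:
    def test_separable_covariate_reaches_high_training_auc(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=400), "z": rng.normal(size=400)})
        t["response"] = (t["x"] > 0).astype(int)
        fit = fit_brt(t, ["x", "z"], BRTConfig(300, 1, 0.1, 1.0), seed=2)
        auc = roc_auc_score(t["response"], fit.predict(t[["x", "z"]].to_numpy()))
        assert auc > 0.995

    def test_zero_trees_predicts_prevalence(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(0, 3, 0.1, 0.5), seed=0)
        p = fit.predict(toy_table[COVS].to_numpy())
        np.testing.assert_allclose(p, toy_table["response"].mean(), atol=1e-9)

    def test_single_class_rejected(self, toy_table):
        t = toy_table.copy()
        t["response"] = 1
        with pytest.raises(ValueError):
            fit_brt(t, COVS, BRTConfig(10, 1, 0.1, 0.5), seed=0)

    def test_deterministic_under_fixed_seed(self, toy_table):
        X = toy_table[COVS].to_numpy()
        a = fit_brt(toy_table, COVS, BRTConfig(50, 3, 0.1, 0.5), seed=9).predict(X)
        b = fit_brt(toy_table, COVS, BRTConfig(50, 3, 0.1, 0.5), seed=9).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_row_permutation_invariance_with_full_bag(self, toy_table):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(toy_table))
        grid_X = toy_table[COVS].to_numpy()
        a = fit_brt(toy_table, COVS, BRTConfig(40, 3, 0.1, 1.0), seed=5).predict(grid_X)
        b = fit_brt(toy_table.iloc[perm].reset_index(drop=True), COVS, BRTConfig(40, 3, 0.1, 1.0), seed=5).predict(grid_X)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_predictions_in_unit_interval(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(150, 5, 0.1, 0.5), seed=1)
        p = fit.predict(toy_table[COVS].to_numpy())
        assert (p > 0).all() and (p < 1).all()

    def test_staged_decision_matches_truncated_ensemble(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(100, 3, 0.1, 0.5), seed=4)
        X = toy_table[COVS].to_numpy()[:50]
        staged = fit.staged_decision(X, [50, 100])
        np.testing.assert_allclose(staged[50], fit.decision(X, n_trees=50), atol=1e-12)
        np.testing.assert_allclose(staged[100], fit.decision(X), atol=1e-12)

    def test_missing_values_handled(self, toy_table):
        t = toy_table.copy()
        t.loc[t.index[:100], "w"] = np.nan
        fit = fit_brt(t, COVS, BRTConfig(60, 3, 0.1, 0.5), seed=0)
        p = fit.predict(t[COVS].to_numpy())
        assert np.isfinite(p).all()

    def test_agrees_with_sklearn_oracle_on_holdout(self, toy_table):
        from sklearn.ensemble import GradientBoostingClassifier

        train = toy_table.iloc[:400]
        test = toy_table.iloc[400:]
        fit = fit_brt(train, COVS, BRTConfig(300, 3, 0.05, 1.0), seed=0)
        ours = roc_auc_score(test["response"], fit.predict(test[COVS].to_numpy()))
        gb = GradientBoostingClassifier(n_estimators=300, max_leaf_nodes=4, learning_rate=0.05, random_state=0)
        gb.fit(train[COVS], train["response"])
        theirs = roc_auc_score(test["response"], gb.predict_proba(test[COVS])[:, 1])
        assert abs(ours - theirs) < 0.05


class TestInfluence:
    def test_influence_normalization(self, toy_table):
        t = importance_control(toy_table, seed=1)
        fit = fit_brt(t, COVS + [RANDOM_CONTROL], BRTConfig(100, 3, 0.1, 0.5), seed=2)
        infl = relative_influence(fit)
        assert abs(infl.sum() - 100.0) < 1e-6
        assert (infl >= 0).all()
        assert infl["x"] > infl[RANDOM_CONTROL]

    def test_single_covariate_gets_all_influence(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=200)})
        t["response"] = (t["x"] > 0).astype(int)
        fit = fit_brt(t, ["x"], BRTConfig(50, 1, 0.1, 1.0), seed=0)
        infl = relative_influence(fit)
        np.testing.assert_allclose(infl["x"], 100.0)

    def test_never_split_covariate_zero(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=300), "c": np.ones(300)})
        t["response"] = (t["x"] > 0).astype(int)
        fit = fit_brt(t, ["x", "c"], BRTConfig(50, 1, 0.1, 1.0), seed=0)
        assert relative_influence(fit)["c"] == 0.0


class TestImportanceControl:
    def test_adds_uniform_integers_1_to_100(self, toy_table):
        t = importance_control(toy_table, seed=7)
        assert RANDOM_CONTROL in t.columns
        assert t[RANDOM_CONTROL].min() >= 1 and t[RANDOM_CONTROL].max() <= 100
        np.testing.assert_array_equal(t[RANDOM_CONTROL], np.round(t[RANDOM_CONTROL]))

    def test_deterministic(self, toy_table):
        a = importance_control(toy_table, seed=7)
        b = importance_control(toy_table, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestPartialDependence:
    def test_ignored_covariate_gives_flat_curve(self, toy_table):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=300), "c": rng.normal(size=300)})
        t["response"] = (t["x"] > 0).astype(int)
        fit = fit_brt(t, ["x", "c"], BRTConfig(50, 1, 0.1, 1.0), seed=0)
        curve = partial_dependence(fit, "c", np.linspace(-2, 2, 7))
        assert curve["prob"].std() < 1e-6

    def test_monotone_response_gives_monotone_curve(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(200, 3, 0.05, 1.0), seed=0)
        curve = partial_dependence(fit, "x", np.linspace(-2, 2, 11))
        assert (np.diff(curve["logit"]) >= -1e-9).all()

    def test_matches_brute_force_averaging(self, toy_table):
        t = toy_table.iloc[:200]
        fit = fit_brt(t, COVS, BRTConfig(80, 3, 0.1, 0.5), seed=1)
        grid = np.linspace(-1.5, 1.5, 5)
        curve = partial_dependence(fit, "z", grid)
        X = t[COVS].to_numpy().copy()
        j = COVS.index("z")
        for gi, v in enumerate(grid):
            Xv = X.copy()
            Xv[:, j] = v
            brute = fit.decision(Xv).mean()
            np.testing.assert_allclose(curve["logit"].iloc[gi], brute, atol=1e-9)

    def test_unknown_covariate_rejected(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(10, 1, 0.1, 0.5), seed=1)
        with pytest.raises(ValueError):
            partial_dependence(fit, "nope", np.array([0.0]))


class TestTuning:
    def test_grid_has_36_combinations(self):
        assert len(BRTGrid().combinations()) == 36
        assert WINTER2019.n_trees == 1050 and WINTER2019.tree_complexity == 5

    def test_folds_are_individuals_and_holdout_is_clean(self, toy_table, monkeypatch):
        recorded = []
        orig = brt.fit_brt

        def spy(table, covariates, config, seed=0, min_samples_leaf=5, row_index=None):
            if row_index is not None:
                recorded.append(set(table.iloc[row_index]["individual_id"]))
            return orig(table, covariates, config, seed=seed, min_samples_leaf=min_samples_leaf, row_index=row_index)

        monkeypatch.setattr(brt, "fit_brt", spy)
        grid = BRTGrid(tree_counts=(20, 40), tree_complexity=(1,), learning_rate=(0.1,), bag_fraction=(0.5,))
        config, cv, scan = tune_brt(toy_table, COVS, grid=grid, seed=0, min_trees=10)
        all_ids = set(toy_table["individual_id"])
        assert len(cv.fold_ids) == len(all_ids)
        # every training set omits exactly one individual entirely
        for ids in recorded:
            assert len(all_ids - ids) == 1

    def test_selection_respects_grid_and_tiebreak_priority(self, toy_table):
        grid = BRTGrid(tree_counts=(20, 40, 60), tree_complexity=(1, 3), learning_rate=(0.1, 0.05), bag_fraction=(0.5,))
        config, cv, scan = tune_brt(toy_table, COVS, grid=grid, seed=0, min_trees=10)
        assert config.n_trees in grid.tree_counts
        assert config.tree_complexity in grid.tree_complexity
        assert 0 <= cv.mean_auc <= 1
        best = scan[scan["n_trees"] > 10]["cv_auc"].max()
        assert np.isclose(
            scan[
                (scan["tree_complexity"] == config.tree_complexity)
                & (scan["learning_rate"] == config.learning_rate)
                & (scan["n_trees"] == config.n_trees)
            ]["cv_auc"].iloc[0],
            best,
        )

    def test_single_individual_rejected(self, toy_table):
        t = toy_table.copy()
        t["individual_id"] = "only"
        with pytest.raises(ValueError):
            tune_brt(t, COVS, seed=0)


def _flat_stack(n_days=4, nlat=6, nlon=6, value=0.5):
    dates = pd.date_range("2019-03-01", periods=n_days)
    ones = np.full((n_days, nlat, nlon), value)
    ds = xr.Dataset(
        {
            "land": (("lat", "lon"), np.zeros((nlat, nlon), bool)),
            "x": (("time", "lat", "lon"), ones.copy()),
            "z": (("time", "lat", "lon"), ones.copy()),
            "w": (("time", "lat", "lon"), ones.copy()),
        },
        coords={"time": dates, "lat": np.arange(nlat) * 0.1 - 65, "lon": np.arange(nlon) * 0.1 - 62},
        attrs={"cell_deg": 0.1, "lon0": -62.05, "lat0": -65.05},
    )
    return ds


class TestBootstrapAndMaps:
    def test_bootstrap_count_and_median_bounds(self, toy_table):
        fits = bootstrap_ensemble(toy_table, COVS, BRTConfig(30, 1, 0.1, 0.5), n=8, seed=0)
        assert len(fits) == 8
        X = toy_table[COVS].to_numpy()[:30]
        preds = np.stack([f.predict(X) for f in fits])
        med = np.median(preds, axis=0)
        assert (med >= preds.min(axis=0)).all() and (med <= preds.max(axis=0)).all()

    def test_identical_fits_give_zero_ci_range(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(30, 1, 0.1, 0.5), seed=0)
        maps = predict_maps([fit] * 10, _flat_stack(), pd.date_range("2019-03-01", periods=2))
        rng95 = maps["suitability_ci_range"].values
        np.testing.assert_allclose(rng95[np.isfinite(rng95)], 0.0, atol=1e-12)

    def test_constant_covariates_give_spatially_constant_maps(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(30, 3, 0.1, 0.5), seed=0)
        maps = predict_maps([fit], _flat_stack(), pd.date_range("2019-03-01", periods=1))
        m = maps["suitability_median"].values[0]
        assert np.nanstd(m) < 1e-12

    def test_monthly_mean_of_identical_days_equals_daily(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(30, 3, 0.1, 0.5), seed=0)
        maps = predict_maps([fit], _flat_stack(n_days=5), pd.date_range("2019-03-01", periods=5))
        daily = maps["suitability_median"].values[0]
        monthly = maps["monthly_median"].sel(month=3).values
        np.testing.assert_allclose(monthly, daily, atol=1e-12)

    def test_date_outside_stack_rejected(self, toy_table):
        fit = fit_brt(toy_table, COVS, BRTConfig(10, 1, 0.1, 0.5), seed=0)
        with pytest.raises(ValueError):
            predict_maps([fit], _flat_stack(), pd.date_range("2030-01-01", periods=1))
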