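"""Tests for the from-scratch regression models.

The CART and boosting implementations are checked against independent
oracles written here: an exhaustive split search over every (feature,
midpoint-threshold) pair, a recursive oracle tree built on it, and a plain
sequential-residual boosting loop.  Baselines with closed forms are checked
against scikit-learn.
"""

import numpy as np
import pytest

from ppgglu import (
    BaggedTrees,
    GradientBoostedRegressor,
    KNNRegressor,
    LinearRegressor,
    RegressionTree,
    RidgeRegressor,
    ValidationError,
    benchmark_models,
    calibrate_personal,
    fit_baseline,
    fit_gbdt,
    fit_tree,
    load_model,
    make_model,
    predict,
    save_model,
)
from ppgglu.pipeline import feature_matrix

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-10


def oracle_best_split(X, y, min_leaf):
    """Exhaustive search over every (feature, midpoint) candidate; ties go
    to the lowest feature index, then the lowest threshold."""
    n, d = X.shape
    best = None  # (sse, feature, threshold)
    tol = _TIE_TOL * max(1.0, float(np.sum((y - y.mean()) ** 2)))
    for f in range(d):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2)
            if best is None or sse < best[0] - tol:
                best = (sse, f, thr)
    if best is None:
        return None
    return best[1], best[2]


def oracle_tree(X, y, max_depth, min_leaf):
    """Recursive CART oracle returning a nested-tuple tree."""
    if (
        max_depth == 0
        or len(y) < 2 * min_leaf
        or np.ptp(y) == 0
        or (split := oracle_best_split(X, y, min_leaf)) is None
    ):
        return float(np.mean(y))
    f, thr = split
    mask = X[:, f] <= thr
    if mask.all() or not mask.any():
        return float(np.mean(y))
    return (
        f,
        thr,
        oracle_tree(X[mask], y[mask], max_depth - 1, min_leaf),
        oracle_tree(X[~mask], y[~mask], max_depth - 1, min_leaf),
    )


def oracle_tree_predict(node, row):
    while isinstance(node, tuple):
        f, thr, left, right = node
        node = left if row[f] <= thr else right
    return node


def oracle_gbdt_predict(X, y, X_new, n_rounds, lr, max_depth, min_leaf):
    """Plain sequential-residual boosting loop over oracle trees."""
    f0 = float(np.mean(y))
    fit_pred = np.full(len(y), f0)
    new_pred = np.full(len(X_new), f0)
    for _ in range(n_rounds):
        tree = oracle_tree(X, y - fit_pred, max_depth, min_leaf)
        fit_pred = fit_pred + lr * np.array([oracle_tree_predict(tree, r) for r in X])
        new_pred = new_pred + lr * np.array([oracle_tree_predict(tree, r) for r in X_new])
    return new_pred


def _random_dataset(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    d = int(rng.integers(1, 4))
    # values on a coarse grid keep split thresholds away from float
    # knife-edges without reducing the structural variety of the fixtures
    X = rng.integers(-8, 9, size=(n, d)) / 4.0
    y = rng.integers(-20, 21, size=n) / 5.0
    return X, y


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------


class TestRegressionTree:
    def test_step_function_fixture(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = fit_tree(X, y, max_depth=1, min_samples_leaf=1)
        assert tree.root_.feature == 0
        assert tree.root_.threshold == 1.5
        np.testing.assert_array_equal(tree.predict(X), y)

    def test_constant_response_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        tree = fit_tree(X, np.full(10, 3.3))
        assert tree.root_.is_leaf
        np.testing.assert_array_equal(tree.predict(X), np.full(10, 3.3))

    def test_depth_zero_predicts_mean(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        tree = fit_tree(X, y, max_depth=0)
        np.testing.assert_allclose(tree.predict(X), np.mean(y))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError, match="mismatch"):
            fit_tree(np.zeros((3, 1)), np.zeros(4))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle(self, seed):
        """Full-tree predictions equal the exhaustive-search oracle on all
        small fixtures (n <= 12, d <= 3)."""
        X, y = _random_dataset(seed)
        for depth in (1, 2, 3):
            mine = fit_tree(X, y, max_depth=depth, min_samples_leaf=2)
            ref = oracle_tree(X, y, depth, 2)
            got = mine.predict(X)
            want = np.array([oracle_tree_predict(ref, r) for r in X])
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_serialization_round_trip(self):
        X, y = _random_dataset(7)
        tree = fit_tree(X, y, max_depth=3)
        clone = RegressionTree.from_dict(tree.to_dict())
        np.testing.assert_array_equal(clone.predict(X), tree.predict(X))


# ---------------------------------------------------------------------------
# Gradient boosting
# ---------------------------------------------------------------------------


@pytest.fixture()
def eight_rows():
    X = np.array(
        [[0.0, 1.0], [1.0, 0.5], [2.0, -0.5], [3.0, 2.0],
         [4.0, 1.5], [5.0, -1.0], [6.0, 0.0], [7.0, 2.5]]
    )
    y = np.array([5.0, 5.2, 4.8, 6.1, 6.0, 4.5, 5.5, 6.6])
    return X, y


class TestGradientBoosting:
    def test_matches_sequential_residual_oracle(self, eight_rows):
        """Predictions on the 8-row fixture equal a hand-run boosting loop
        (N = 3, learning rate 0.5, depth 2)."""
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=3, learning_rate=0.5, max_depth=2,
                         min_samples_leaf=2)
        want = oracle_gbdt_predict(X, y, X, 3, 0.5, 2, 2)
        np.testing.assert_allclose(model.predict(X), want, atol=1e-12)
        X_new = X + 0.25
        want_new = oracle_gbdt_predict(X, y, X_new, 3, 0.5, 2, 2)
        np.testing.assert_allclose(model.predict(X_new), want_new, atol=1e-12)

    def test_zero_rounds_predicts_mean(self, eight_rows):
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=0)
        np.testing.assert_allclose(model.predict(X), np.mean(y))

    def test_single_full_tree_interpolates(self, eight_rows):
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=1, learning_rate=1.0, max_depth=None,
                         min_samples_leaf=1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-12)

    def test_residual_log_length_and_first_residual(self, eight_rows):
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=5, learning_rate=0.3)
        assert len(model.residual_log_) == 5
        np.testing.assert_allclose(model.residual_log_[0], y - np.mean(y))

    def test_training_mse_non_increasing(self):
        for seed in range(5):
            X, y = _random_dataset(seed + 100)
            model = fit_gbdt(X, y, n_rounds=20, learning_rate=0.4, max_depth=2,
                             min_samples_leaf=1)
            mse = np.array(model.train_mse_)
            assert np.all(np.diff(mse) <= 1e-12)

    @pytest.mark.parametrize("kwargs", [{"learning_rate": 0.0},
                                        {"learning_rate": 1.5},
                                        {"n_rounds": -1}])
    def test_invalid_hyperparameters(self, kwargs):
        with pytest.raises(ValidationError):
            GradientBoostedRegressor(**kwargs)

    def test_empty_prediction_input(self, eight_rows):
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=2)
        assert predict(model, np.empty((0, 2))).shape == (0,)

    def test_row_permutation_invariance(self, eight_rows):
        X, y = eight_rows
        perm = np.random.default_rng(0).permutation(len(y))
        a = fit_gbdt(X, y, n_rounds=10).predict(X)
        b = fit_gbdt(X[perm], y[perm], n_rounds=10).predict(X)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_close_to_sklearn_gbdt(self):
        """Statistical cross-check: scikit-learn's gradient boosting (same
        loss, depth and learning rate; friedman splits) lands close."""
        from sklearn.ensemble import GradientBoostingRegressor as SkGBDT

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.3, 60)
        mine = fit_gbdt(X, y, n_rounds=50, learning_rate=0.1, max_depth=2,
                        min_samples_leaf=1)
        skl = SkGBDT(n_estimators=50, learning_rate=0.1, max_depth=2,
                     min_samples_leaf=1).fit(X, y)
        Xt = rng.normal(size=(40, 3))
        diff = np.abs(mine.predict(Xt) - skl.predict(Xt))
        assert np.mean(diff) < 0.15 * np.std(y)

    def test_serialization_round_trip(self, eight_rows, tmp_path):
        X, y = eight_rows
        model = fit_gbdt(X, y, n_rounds=4)
        path = tmp_path / "model.json"
        save_model(model, path, feature_names=["a", "b"], seed=1)
        clone = load_model(path)
        np.testing.assert_array_equal(clone.predict(X), model.predict(X))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


class TestBaselines:
    def test_linear_recovers_exact_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = 2.0 + X @ [1.5, -0.5, 3.0]
        model = fit_baseline("linear", X, y)
        np.testing.assert_allclose(model.coef_, [1.5, -0.5, 3.0], atol=1e-8)
        assert model.intercept_ == pytest.approx(2.0, abs=1e-8)

    def test_ridge_limits_to_linear(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.normal(0, 0.1, 40)
        lin = fit_baseline("linear", X, y)
        rid = fit_baseline("ridge", X, y, alpha=1e-10)
        np.testing.assert_allclose(rid.coef_, lin.coef_, atol=1e-6)

    def test_linear_and_ridge_match_sklearn(self):
        from sklearn.linear_model import LinearRegression, Ridge

        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        np.testing.assert_allclose(
            fit_baseline("linear", X, y).predict(X),
            LinearRegression().fit(X, y).predict(X),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            fit_baseline("ridge", X, y, alpha=2.5).predict(X),
            Ridge(alpha=2.5).fit(X, y).predict(X),
            atol=1e-8,
        )

    def test_knn_with_k_equals_n_predicts_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = fit_baseline("knn", X, y, k=15)
        np.testing.assert_allclose(model.predict(X), np.mean(y), atol=1e-12)

    def test_knn_matches_sklearn(self):
        from sklearn.neighbors import KNeighborsRegressor

        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        Xt = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            fit_baseline("knn", X, y, k=5).predict(Xt),
            KNeighborsRegressor(n_neighbors=5).fit(X, y).predict(Xt),
            atol=1e-10,
        )

    def test_unknown_name_lists_options(self):
        with pytest.raises(ValidationError, match="linear"):
            fit_baseline("svm", np.zeros((5, 1)), np.zeros(5))

    def test_bagged_trees_seeded_determinism(self, small_xy):
        X, y = small_xy
        a = fit_baseline("rfr", X, y, seed=5, n_estimators=10).predict(X)
        b = fit_baseline("rfr", X, y, seed=5, n_estimators=10).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_permutation_invariance_deterministic_models(self, eight_rows=None):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        for name in ("linear", "ridge", "knn"):
            a = fit_baseline(name, X, y).predict(X)
            b = fit_baseline(name, X[perm], y[perm]).predict(X)
            np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


class TestBenchmark:
    def test_zero_noise_tree_ensembles_reach_high_r2(self, noiseless_table):
        X, y, _ = feature_matrix(noiseless_table)
        table = benchmark_models(X, y, seed=0,
                                 models=("gbdt", "bagging", "dtr"),
                                 model_params={"bagging": {"n_estimators": 30}})
        assert (table.loc[["gbdt", "bagging"], "R2"] > 0.99).all()

    def test_label_permutation_destroys_skill(self, small_xy):
        """Null simulation: with labels permuted, average held-out R2 across
        permutation draws is at (or below) chance for every model."""
        X, y = small_xy
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(5):
            y_perm = rng.permutation(y)
            tables.append(
                benchmark_models(
                    X, y_perm, test_fraction=0.5, seed=1,
                    models=("gbdt", "linear", "knn", "dtr"),
                    model_params={"gbdt": {"n_rounds": 50}},
                )
            )
        mean_r2 = sum(t["R2"] for t in tables) / len(tables)
        assert (mean_r2 <= 0.1).all()

    def test_same_seed_identical_table(self, small_xy):
        X, y = small_xy
        kwargs = dict(seed=3, models=("gbdt", "linear", "knn"),
                      model_params={"gbdt": {"n_rounds": 30}})
        a = benchmark_models(X, y, **kwargs)
        b = benchmark_models(X, y, **kwargs)
        assert a.equals(b)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError, match="20"):
            benchmark_models(np.zeros((10, 2)), np.zeros(10))

    def test_metric_columns(self, small_xy):
        X, y = small_xy
        table = benchmark_models(X, y, seed=0, models=("linear", "knn"))
        assert list(table.columns) == ["MSE", "RMSE", "MAE", "MARD", "R2"]


# ---------------------------------------------------------------------------
# Personal calibration
# ---------------------------------------------------------------------------


def _population_model(seed=0, n=150):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = 5.0 + X @ [0.5, -0.3, 0.2] + rng.normal(0, 0.1, n)
    model = fit_gbdt(X, y, n_rounds=80, learning_rate=0.1)
    return model, rng


class TestPersonalCalibration:
    def test_affine_removes_constant_offset(self):
        model, rng = _population_model()
        Xp = rng.normal(size=(10, 3))
        yp = 5.0 + Xp @ [0.5, -0.3, 0.2] + 1.0  # person runs +1 mmol/L high
        calibrated = calibrate_personal(model, Xp, yp, strategy="affine")
        Xt = rng.normal(size=(30, 3))
        yt = 5.0 + Xt @ [0.5, -0.3, 0.2] + 1.0
        offset_left = np.mean(yt - calibrated.predict(Xt))
        assert abs(offset_left) < 0.1

    def test_single_pair_gives_intercept_only(self):
        model, rng = _population_model()
        Xp = rng.normal(size=(1, 3))
        yp = np.array([7.0])
        calibrated = calibrate_personal(model, Xp, yp, strategy="affine")
        assert calibrated.scale == 1.0
        assert calibrated.predict(Xp)[0] == pytest.approx(7.0, abs=1e-9)

    def test_matching_person_barely_changes_mard(self):
        """Calibrating on a person drawn from the population distribution
        moves held-out MARD by less than one percentage point."""
        from ppgglu.evaluation import compute_metrics

        model, rng = _population_model()
        Xp = rng.normal(size=(10, 3))
        yp = 5.0 + Xp @ [0.5, -0.3, 0.2] + rng.normal(0, 0.1, 10)
        calibrated = calibrate_personal(model, Xp, yp, strategy="boost")
        Xt = rng.normal(size=(60, 3))
        yt = 5.0 + Xt @ [0.5, -0.3, 0.2] + rng.normal(0, 0.1, 60)
        before = compute_metrics(yt, model.predict(Xt)).mard
        after = compute_metrics(yt, calibrated.predict(Xt)).mard
        assert abs(after - before) < 1.0

    def test_boost_strategy_fits_personal_offset(self):
        model, rng = _population_model()
        Xp = rng.normal(size=(12, 3))
        yp = 5.0 + Xp @ [0.5, -0.3, 0.2] + 1.0
        calibrated = calibrate_personal(model, Xp, yp, strategy="boost",
                                        n_rounds=50)
        resid = np.mean(np.abs(yp - calibrated.predict(Xp)))
        assert resid < 0.25

    def test_zero_pairs_rejected(self):
        model, _ = _population_model()
        with pytest.raises(ValidationError):
            calibrate_personal(model, np.empty((0, 3)), np.empty(0))

    def test_unknown_strategy(self):
        model, rng = _population_model()
        with pytest.raises(ValidationError, match="boost"):
            calibrate_personal(model, np.zeros((2, 3)), np.ones(2), strategy="huh")
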