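"""Reference gradient boosted trees: loss families, CART split search with
missing-direction handling, the boosting loop, early stopping and the
cross-adapter sanity band."""

import math

import numpy as np
import pytest

from saeboost.boosting import (
    GBTConfig,
    GBTModel,
    best_round,
    boost,
    fit_cart,
    loss_family,
    select_rounds_by_cv,
)
from saeboost.predictors import ReferenceGBT, XGBoostPredictor


class TestLossFamilies:
    def test_squared_constant_init_is_the_mean(self):
        loss = loss_family("squared")
        assert loss.constant_init(np.array([1.0, 1.0, 0.0, 1.0])) == pytest.approx(0.75)

    def test_logistic_constant_init_is_log_odds(self):
        loss = loss_family("logistic")
        y = np.array([1.0, 1.0, 1.0, 0.0])
        assert loss.constant_init(y) == pytest.approx(math.log(3), abs=1e-9)

    def test_logistic_negative_gradient_at_zero_score(self):
        loss = loss_family("logistic")
        g = loss.negative_gradient(np.array([1.0]), np.array([0.0]))
        assert g[0] == pytest.approx(0.5)

    def test_squared_negative_gradient_is_residual(self):
        loss = loss_family("squared")
        y, f = np.array([2.0, -1.0]), np.array([0.5, 0.5])
        np.testing.assert_allclose(loss.negative_gradient(y, f), y - f)

    def test_logistic_leaf_newton_step_single_example(self):
        loss = loss_family("logistic")
        # one example, y=1, current raw score 0 => p=0.5 => (1-0.5)/0.25 = 2
        assert loss.leaf_estimate(np.array([1.0]), np.array([0.0])) == pytest.approx(2.0)

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError, match="unknown loss"):
            loss_family("hinge")


class TestCart:
    def test_constant_targets_give_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        tree = fit_cart(X, np.full(10, 2.0), GBTConfig(min_leaf_size=1))
        assert len(tree.nodes) == 1
        assert tree.nodes[0].value == pytest.approx(2.0)

    def test_separable_threshold_split_reaches_zero_sse(self):
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        tree = fit_cart(X, y, GBTConfig(max_depth=1, min_leaf_size=1))
        root = tree.nodes[0]
        assert 3.0 < root.threshold < 7.0
        preds = tree.predict(X)
        assert np.sum((y - preds) ** 2) == pytest.approx(0.0)

    def test_missing_direction_chosen_by_exhaustive_oracle(self):
        """Target depends on missingness itself; the chosen root split must
        match a brute-force enumeration over (threshold, direction) and beat
        both forced routings."""
        X = np.array([[1.0], [2.0], [3.0], [4.0],
                      [np.nan], [np.nan], [np.nan], [np.nan]])
        y = np.array([0.0, 0.0, 1.0, 1.0, 5.0, 5.0, 5.0, 5.0])

        def sse(groups):
            return sum(((g - g.mean()) ** 2).sum() for g in groups if len(g))

        obs = ~np.isnan(X[:, 0])
        xo = X[obs, 0]
        best = (np.inf, None, None)
        per_direction_best = {True: np.inf, False: np.inf}
        for t in (1.5, 2.5, 3.5):
            for miss_left in (True, False):
                left = np.where(np.isnan(X[:, 0]), miss_left, X[:, 0] <= t)
                s = sse([y[left], y[~left]])
                per_direction_best[miss_left] = min(per_direction_best[miss_left], s)
                if s < best[0] - 1e-12:
                    best = (s, t, miss_left)

        tree = fit_cart(X, y, GBTConfig(max_depth=1, min_leaf_size=1))
        root = tree.nodes[0]
        assert root.feature == 0
        assert root.threshold == pytest.approx(best[1])
        assert root.missing_left == best[2]
        # routing missing to its own side strictly beats the forced alternative
        assert best[0] < per_direction_best[not best[2]] - 1e-12

    def test_categorical_one_vs_rest_split(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0], [1.0], [2.0]])
        y = np.array([5.0, 5.0, 1.0, 1.0, 1.0, 1.0])
        tree = fit_cart(X, y, GBTConfig(max_depth=1, min_leaf_size=1),
                        categorical=np.array([True]))
        root = tree.nodes[0]
        assert root.level == pytest.approx(0.0)
        assert np.sum((tree.predict(X) - y) ** 2) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_cart(np.empty((0, 2)), np.empty(0), GBTConfig())


class TestBoost:
    def test_zero_rounds_logistic_predicts_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.7).astype(float)
        model = boost(X, y, GBTConfig(loss="logistic", n_rounds=0))
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-12)

    def test_single_stage_exact_fit_on_noiseless_separable_data(self):
        rng = np.random.default_rng(1)
        X = rng.choice([0.0, 1.0, 2.0, 3.0], size=(64, 2))
        y = 3.0 * X[:, 0] - X[:, 1]  # piecewise-constant in the 16 cells
        config = GBTConfig(loss="squared", learning_rate=1.0, n_rounds=1,
                           max_depth=8, min_leaf_size=1)
        model = boost(X, y, config)
        assert np.mean((model.predict(X) - y) ** 2) == pytest.approx(0.0, abs=1e-18)

    def test_training_loss_nonincreasing_squared(self):
        rng = np.random.default_rng(2)
        for lr in (0.1, 0.5, 1.0):
            X = rng.normal(size=(200, 5))
            y = X[:, 0] ** 2 + np.sin(X[:, 1]) + rng.normal(scale=0.3, size=200)
            config = GBTConfig(loss="squared", learning_rate=lr, n_rounds=25,
                               max_depth=3, min_leaf_size=5)
            model = boost(X, y, config)
            raw = np.full(200, model.f0)
            losses = []
            for tree in model.trees:
                raw += lr * tree.predict(X)
                losses.append(np.sum(0.5 * (y - raw) ** 2))
            assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_logistic_predictions_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 4))
        y = (rng.random(300) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        model = boost(X, y, GBTConfig(loss="logistic", n_rounds=40, max_depth=4,
                                      min_leaf_size=2))
        p = model.predict(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_nonbinary_labels_rejected_under_logistic(self):
        X = np.zeros((4, 1))
        with pytest.raises(ValueError, match="binary"):
            boost(X, np.array([0.0, 0.5, 1.0, 1.0]), GBTConfig(loss="logistic"))

    def test_all_missing_row_receives_linked_constant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3))
        X[rng.random((100, 3)) < 0.2] = np.nan
        y = (rng.random(100) < 0.6).astype(float)
        model = boost(X, y, GBTConfig(loss="logistic", n_rounds=10, min_leaf_size=5))
        blank = np.full((1, 3), np.nan)
        expected = 1 / (1 + np.exp(-model.f0))
        assert model.predict(blank)[0] == pytest.approx(expected)

    def test_serialization_round_trips_bit_exactly(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 4))
        X[rng.random((150, 4)) < 0.1] = np.nan
        y = (rng.random(150) < 0.5).astype(float)
        model = boost(X, y, GBTConfig(loss="logistic", n_rounds=15, min_leaf_size=5))
        clone = GBTModel.from_json(model.to_json())
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))


class TestEarlyStopping:
    def test_best_round_is_argmin_of_injected_sequence(self):
        assert best_round([0.50, 0.40, 0.45]) == 2

    def test_pure_noise_selects_few_rounds(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 3))
        y = rng.normal(size=150)
        config = GBTConfig(loss="squared", learning_rate=0.1, max_depth=2,
                           min_leaf_size=5, patience=10, max_rounds=100, seed=7)
        t_star, curve = select_rounds_by_cv(X, y, config)
        assert t_star <= 1 + config.patience

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 3))
        y = X[:, 0] + rng.normal(scale=0.5, size=120)
        config = GBTConfig(loss="squared", learning_rate=0.2, max_depth=2,
                           min_leaf_size=5, patience=5, max_rounds=60, seed=9)
        t1, c1 = select_rounds_by_cv(X, y, config)
        t2, c2 = select_rounds_by_cv(X, y, config)
        assert t1 == t2
        np.testing.assert_array_equal(c1, c2)

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ValueError, match="fewer rows"):
            select_rounds_by_cv(np.zeros((3, 1)), np.zeros(3), GBTConfig(cv_folds=5))


def test_reference_and_library_booster_agree_within_band():
    """Held-out MSE of the reference implementation and the xgboost adapter
    within 10% of each other at matched depth-2, alpha=0.1, 50 rounds
    (regularization details differ, so no bit-equality)."""
    import pandas as pd

    rng = np.random.default_rng(10)
    n = 500
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
    y = (
        X["f0"].to_numpy() * 2
        + np.sin(2 * X["f1"].to_numpy())
        + rng.normal(scale=0.3, size=n)
    )
    train, test = np.arange(300), np.arange(300, n)

    ref = ReferenceGBT(GBTConfig(loss="squared", learning_rate=0.1, n_rounds=50,
                                 max_depth=2, min_leaf_size=5))
    ref.fit(X.iloc[train], y[train])
    lib = XGBoostPredictor(loss="squared", learning_rate=0.1, n_rounds=50, max_depth=2)
    lib.fit(X.iloc[train], y[train])

    mse_ref = np.mean((ref.predict(X.iloc[test]) - y[test]) ** 2)
    mse_lib = np.mean((lib.predict(X.iloc[test]) - y[test]) ** 2)
    assert abs(mse_ref - mse_lib) / min(mse_ref, mse_lib) < 0.10
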