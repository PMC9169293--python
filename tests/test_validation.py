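"""Out-of-sample validation: folds, metrics, ROC/calibration curves and
region-estimate comparison."""

import numpy as np
import pandas as pd
import pytest

from saeboost.predictors import NullPredictor, XGBoostPredictor
from saeboost.validation import (
    DIFF_BREAKS,
    auc_pairwise,
    calibration_bins,
    compare_region_estimates,
    compute_metrics,
    kfold_assignments,
    kfold_oos_predictions,
    roc_points,
)


class TestKFold:
    def test_folds_partition_with_balanced_sizes(self):
        folds = kfold_assignments(10, 5, seed=0)
        sizes = np.bincount(folds)
        assert sizes.tolist() == [2, 2, 2, 2, 2]
        folds = kfold_assignments(103, 5, seed=1)
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1 and sizes.sum() == 103

    def test_null_factory_predicts_training_fold_means(self):
        rng = np.random.default_rng(3)
        y = rng.random(50)
        X = pd.DataFrame({"z": np.zeros(50)})
        preds = kfold_oos_predictions(X, y, lambda s: NullPredictor(), k=5, seed=7)
        folds = kfold_assignments(50, 5, seed=7)
        for i in range(5):
            expected = y[folds != i].mean()  # direct recomputation
            assert preds[folds == i] == pytest.approx(expected)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_assignments(10, 1)


class TestMetrics:
    def test_hand_computed_brier_and_nll(self):
        labels = np.array([1, 1, 1, 1, 0], dtype=float)
        report = compute_metrics(labels, np.full(5, 0.8))
        assert report.mse == pytest.approx(0.16, abs=1e-9)
        assert report.nll == pytest.approx(0.500402, abs=1e-6)
        assert report.accuracy == pytest.approx(0.8)

    def test_three_row_auc_equals_pairwise_oracle(self):
        labels = np.array([1.0, 0.0, 1.0])
        preds = np.array([0.9, 0.5, 0.4])
        # brute force over the 2 (positive, negative) pairs: one correct
        assert auc_pairwise(labels, preds) == pytest.approx(0.5)
        assert compute_metrics(labels, preds).auc == pytest.approx(0.5)

    def test_auc_matches_brute_force_enumeration_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            labels = (rng.random(50) < 0.4).astype(float)
            if labels.sum() in (0, 50):
                continue
            preds = np.round(rng.random(50), 1)  # force ties
            correct = 0.0
            pairs = 0
            for p_i in preds[labels == 1]:
                for p_j in preds[labels == 0]:
                    pairs += 1
                    correct += 1.0 if p_i > p_j else (0.5 if p_i == p_j else 0.0)
            assert auc_pairwise(labels, preds) == pytest.approx(correct / pairs)

    def test_perfect_predictions(self):
        labels = np.array([0.0, 1.0, 1.0, 0.0])
        report = compute_metrics(labels, labels)
        assert report.mse == 0.0 and report.accuracy == 1.0 and report.auc == 1.0

    def test_null_row_internal_consistency(self):
        """A constant-prevalence predictor with accuracy a has Brier a(1-a)
        and NLL -[a ln a + (1-a) ln(1-a)]; at a=0.801 these are ~0.159 and
        ~0.500, matching the reported null baseline."""
        n, a = 1000, 0.801
        labels = np.zeros(n)
        labels[: int(a * n)] = 1.0
        report = compute_metrics(labels, np.full(n, a))
        assert report.accuracy == pytest.approx(a)
        assert report.mse == pytest.approx(a * (1 - a), abs=1e-12)
        assert report.nll == pytest.approx(-(a * np.log(a) + (1 - a) * np.log(1 - a)), abs=1e-12)
        assert report.mse == pytest.approx(0.160, abs=0.005)
        assert report.nll == pytest.approx(0.500, abs=0.005)
        assert report.auc == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        labels = (rng.random(200) < 0.3).astype(float)
        preds = rng.random(200)
        perm = rng.permutation(200)
        r1 = compute_metrics(labels, preds)
        r2 = compute_metrics(labels[perm], preds[perm])
        assert r1.to_dict() == pytest.approx(r2.to_dict())

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.0, 1.0]), np.array([0.5, 1.2]))


class TestROC:
    def test_separating_predictions_reach_corner(self):
        labels = np.array([0, 0, 1, 1], dtype=float)
        preds = np.array([0.1, 0.2, 0.8, 0.9])
        curve = roc_points(labels, preds, 100)
        assert ((curve["fpr"] == 0) & (curve["tpr"] == 1)).any()

    def test_constant_predictions_give_only_the_two_corners(self):
        labels = np.array([0, 1, 0, 1], dtype=float)
        curve = roc_points(labels, np.full(4, 0.5), 100)
        pts = set(zip(curve["fpr"], curve["tpr"]))
        assert pts == {(0.0, 0.0), (1.0, 1.0)}

    def test_rates_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(13)
        labels = (rng.random(300) < 0.4).astype(float)
        preds = rng.random(300)
        curve = roc_points(labels, preds, 100)
        assert (np.diff(curve["tpr"]) <= 1e-12).all()
        assert (np.diff(curve["fpr"]) <= 1e-12).all()

    def test_trapezoid_area_close_to_pairwise_auc(self):
        rng = np.random.default_rng(14)
        labels = (rng.random(1000) < 0.5).astype(float)
        preds = np.clip(labels * 0.2 + rng.random(1000) * 0.8, 0, 1)
        curve = roc_points(labels, preds, 100)
        area = -np.trapezoid(curve["tpr"], curve["fpr"])  # fpr decreasing
        assert abs(area - auc_pairwise(labels, preds)) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.ones(5), np.random.random(5))


class TestCalibration:
    def test_constant_prediction_merges_to_single_bin(self):
        labels = np.array([1, 0, 1, 0], dtype=float)
        bins = calibration_bins(labels, np.full(4, 0.5), n_bins=100)
        assert len(bins) == 1
        assert bins["mean_predicted"].iloc[0] == pytest.approx(0.5)
        assert bins["observed_fraction"].iloc[0] == pytest.approx(0.5)

    def test_true_probabilities_are_calibrated_at_scale(self):
        rng = np.random.default_rng(15)
        p = rng.beta(2, 4, 50_000)
        labels = (rng.random(50_000) < p).astype(float)
        bins = calibration_bins(labels, p, n_bins=100)
        gap = (bins["mean_predicted"] - bins["observed_fraction"]).abs().max()
        assert gap < 0.05  # binomial bound per ~500-count bin

    def test_bins_partition_all_rows(self):
        rng = np.random.default_rng(16)
        labels = (rng.random(777) < 0.5).astype(float)
        preds = rng.random(777)
        bins = calibration_bins(labels, preds, n_bins=10)
        assert bins["n"].sum() == 777

    def test_monotone_transform_preserves_bin_membership(self):
        rng = np.random.default_rng(17)
        labels = (rng.random(500) < 0.5).astype(float)
        preds = rng.random(500)
        b1 = calibration_bins(labels, preds, n_bins=20)
        b2 = calibration_bins(labels, preds**2, n_bins=20)  # order-preserving
        np.testing.assert_array_equal(b1["n"], b2["n"])
        np.testing.assert_array_equal(b1["observed_fraction"], b2["observed_fraction"])

    def test_more_bins_than_rows_warns_and_reduces(self):
        with pytest.warns(UserWarning):
            bins = calibration_bins(np.array([0.0, 1.0]), np.array([0.2, 0.8]), n_bins=10)
        assert len(bins) == 2


class TestCompareEstimates:
    def _table(self, estimates):
        return pd.DataFrame(
            {
                "region_code": [f"R{i}" for i in range(len(estimates))],
                "estimate": estimates,
                "n_population": np.arange(1, len(estimates) + 1) * 10,
            }
        )

    def test_identical_tables(self):
        a = self._table(np.linspace(0.1, 0.9, 20))
        out = compare_region_estimates(a, a)
        assert out.pearson_r == pytest.approx(1.0)
        assert out.diff_histogram["percent_of_regions"].iloc[0] == pytest.approx(100.0)

    def test_constant_offset_lands_in_second_bin(self):
        a = self._table(np.linspace(0.1, 0.9, 20))
        b = a.copy()
        b["estimate"] = b["estimate"] + 0.03
        out = compare_region_estimates(a, b)
        assert out.diff_histogram["percent_of_regions"].iloc[1] == pytest.approx(100.0)

    def test_bin_edges_are_quarter_percent_steps(self):
        assert DIFF_BREAKS == (0.0, 0.025, 0.05, 0.075, 0.1, 0.125)

    def test_mismatched_regions_rejected_with_listing(self):
        a = self._table(np.linspace(0.1, 0.9, 5))
        b = self._table(np.linspace(0.1, 0.9, 4))
        with pytest.raises(ValueError, match="R4"):
            compare_region_estimates(a, b)

    def test_mse_stratified_by_region_size_quantile(self):
        a = self._table(np.linspace(0.1, 0.9, 20))
        errs = pd.DataFrame(
            {"region_code": np.repeat(a["region_code"], 3),
             "sq_error": np.tile([0.1, 0.2, 0.3], 20)}
        )
        out = compare_region_estimates(a, a, oos_errors=errs, n_size_quantiles=4)
        assert len(out.mse_by_size_quantile) == 4
        assert out.mse_by_size_quantile["mse"].to_numpy() == pytest.approx([0.2] * 4)


def test_fitted_model_beats_null_out_of_sample():
    """On synthetic data with real signal, out-of-sample MSE of a boosted
    model is no worse than the null model's (50,000-row population)."""
    from saeboost.features import build_design
    from saeboost.synthetic import (
        PopulationConfig,
        SurveyDesign,
        default_surface,
        generate_population,
        sample_survey,
    )

    config = PopulationConfig(n_individuals=50_000, seed=21)
    census, _ = generate_population(config, default_surface())
    pop = sample_survey(census, SurveyDesign(0.2, seed=22))
    X, _ = build_design(pop, spatial_mode="xy", categorical_encoding="onehot")
    y = pop.responses
    X_resp = X.loc[pop.survey_mask]

    oos_model = kfold_oos_predictions(
        X_resp, y,
        lambda s: XGBoostPredictor(loss="logistic", n_rounds=30, max_depth=3, seed=s),
        k=5, seed=23,
    )
    oos_null = kfold_oos_predictions(X_resp, y, lambda s: NullPredictor(), k=5, seed=23)
    mse_model = compute_metrics(y, np.clip(oos_model, 0, 1)).mse
    mse_null = compute_metrics(y, oos_null).mse
    assert mse_model <= mse_null
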