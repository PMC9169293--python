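"""Out-of-sample model validation.

Five-fold cross-validation on the survey respondents, the metric suite
(accuracy, AUC, MSE/Brier, NLL), ROC and calibration curves, and pairwise
comparison of region-estimate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_CLIP = 1e-12

#: Default |difference| histogram edges: 2.5-percentage-point bins.
DIFF_BREAKS = (0.0, 0.025, 0.05, 0.075, 0.1, 0.125)


@dataclass
class MetricsReport:
    mse: float
    accuracy: float | None = None
    auc: float | None = None
    nll: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "mse": self.mse,
            "nll": self.nll,
            "n": self.n,
        }


@dataclass
class CurveSet:
    roc: pd.DataFrame | None = None          # threshold, fpr, tpr
    calibration: pd.DataFrame | None = None  # bin, n, mean_predicted, observed_fraction


def kfold_assignments(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Fold index per row: a seeded uniform shuffle cut into k nearly equal
    parts (sizes differ by at most one)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer rows than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for i, idx in enumerate(np.array_split(perm, k)):
        folds[idx] = i
    return folds


def kfold_oos_predictions(
    X: pd.DataFrame,
    y: np.ndarray,
    model_factory: Callable[[int], object],
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-sample prediction for every respondent: k mutually exclusive
    train/test pairs; each row is predicted by the model whose training fold
    excluded it."""
    y = np.asarray(y, dtype=float)
    folds = kfold_assignments(len(y), k, seed)
    rng = np.random.default_rng(seed)
    preds = np.full(len(y), np.nan)
    for i in range(k):
        test = folds == i
        model = model_factory(int(rng.integers(2**31 - 1)))
        model.fit(X.loc[~test], y[~test])
        preds[test] = np.asarray(model.predict(X.loc[test]), dtype=float)
    assert not np.isnan(preds).any()
    return preds


def auc_pairwise(labels: np.ndarray, predictions: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counted 1/2 — computed via the Mann-Whitney rank statistic, which
    is algebraically the exact pairwise count."""
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both classes")
    ranks = rankdata(predictions)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    labels: np.ndarray, predictions: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """MSE always; accuracy/AUC/NLL when labels are binary.

    mse (the Brier score for binary outcomes) = (1/n) sum (y - f)^2;
    nll = -(1/n) sum [y ln p + (1-y) ln(1-p)] with p clipped 1e-12 from the
    boundary; accuracy classifies with p >= threshold.
    """
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions length mismatch")
    n = len(labels)
    mse = float(np.mean((labels - predictions) ** 2))
    binary = np.isin(labels, (0.0, 1.0)).all()
    if not binary:
        return MetricsReport(mse=mse, n=n)
    if (predictions < 0).any() or (predictions > 1).any():
        raise ValueError("binary metrics need predictions in [0,1]")
    p = np.clip(predictions, _CLIP, 1 - _CLIP)
    nll = float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))
    accuracy = float(np.mean((predictions >= threshold) == labels))
    auc = auc_pairwise(labels, predictions) if 0 < labels.sum() < n else None
    return MetricsReport(mse=mse, accuracy=accuracy, auc=auc, nll=nll, n=n)


def roc_points(
    labels: np.ndarray, predictions: np.ndarray, n_thresholds: int = 100
) -> pd.DataFrame:
    """(FPR, TPR) at evenly spaced thresholds over [0,1], classification
    rule p >= threshold."""
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single class")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    hard = predictions[None, :] >= thresholds[:, None]
    tpr = (hard & (labels == 1)[None, :]).sum(axis=1) / n_pos
    fpr = (hard & (labels == 0)[None, :]).sum(axis=1) / n_neg
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def calibration_bins(
    labels: np.ndarray, predictions: np.ndarray, n_bins: int = 100
) -> pd.DataFrame:
    """Equal-count quantile bins of the predictions with the observed
    fraction of ones per bin.

    Rows are sorted by prediction and cut into ``n_bins`` groups; ties are
    kept together (bins whose boundary falls inside a tie group merge), so
    a constant prediction yields a single bin.
    """
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    n = len(labels)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        warnings.warn(f"n_bins={n_bins} > n={n}; reducing to n")
        n_bins = n
    order = np.argsort(predictions, kind="stable")
    sorted_pred = predictions[order]
    raw_bin = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    # push every member of a tie group into the group's first bin
    group_start = np.zeros(n, dtype=int)
    new_group = np.flatnonzero(np.diff(sorted_pred) > 0) + 1
    group_start[new_group] = 1
    group_id = np.cumsum(group_start)
    first_bin = np.full(group_id.max() + 1, -1, dtype=int)
    for i in range(n):  # first occurrence per group
        if first_bin[group_id[i]] < 0:
            first_bin[group_id[i]] = raw_bin[i]
    bins = first_bin[group_id]
    df = pd.DataFrame(
        {"bin": bins, "prediction": sorted_pred, "label": labels[order]}
    )
    out = df.groupby("bin").agg(
        n=("label", "size"),
        mean_predicted=("prediction", "mean"),
        observed_fraction=("label", "mean"),
    )
    return out.reset_index(drop=True)


@dataclass
class RegionComparison:
    pearson_r: float
    diff_histogram: pd.DataFrame  # bin_low, bin_high, percent_of_regions
    n_regions: int
    mse_by_size_quantile: pd.DataFrame | None = None


def compare_region_estimates(
    est_a: pd.DataFrame,
    est_b: pd.DataFrame,
    diff_breaks: Sequence[float] = DIFF_BREAKS,
    oos_errors: pd.DataFrame | None = None,
    n_size_quantiles: int = 10,
) -> RegionComparison:
    """Compare two region-estimate tables covering the same regions.

    Reports the Pearson correlation of the estimate vectors and the
    histogram of absolute differences over ``diff_breaks`` (percent of
    regions per bin; a final open-ended bin catches larger differences).
    Optionally stratifies individual out-of-sample squared errors
    (``oos_errors``: columns ``region_code``, ``sq_error``) by the region
    population-size quantile.
    """
    a = est_a.set_index("region_code")["estimate"]
    b = est_b.set_index("region_code")["estimate"]
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"region sets differ: only in A {list(only_a[:5])}, only in B {list(only_b[:5])}"
        )
    b = b.loc[a.index]
    r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
    diffs = np.abs(a.to_numpy() - b.to_numpy())
    edges = list(diff_breaks) + [np.inf]
    counts, _ = np.histogram(diffs, bins=edges)
    hist = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "percent_of_regions": 100.0 * counts / len(diffs),
        }
    )

    mse_by_q = None
    if oos_errors is not None:
        sizes = est_a.set_index("region_code")["n_population"]
        qlabels = pd.qcut(sizes.rank(method="first"), n_size_quantiles, labels=False)
        err = oos_errors.copy()
        err["size_quantile"] = err["region_code"].map(
            pd.Series(qlabels.to_numpy(), index=sizes.index)
        )
        mse_by_q = (
            err.groupby("size_quantile")["sq_error"].mean().rename("mse").reset_index()
        )
    return RegionComparison(
        pearson_r=r, diff_histogram=hist, n_regions=len(diffs),
        mse_by_size_quantile=mse_by_q,
    )


def plot_roc(curve: pd.DataFrame, ax=None):
    """Plot a ROC curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["fpr"], curve["tpr"], marker=".")
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    return ax


def plot_calibration(bins: pd.DataFrame, ax=None):
    """Plot a calibration curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(bins["mean_predicted"], bins["observed_fraction"], marker=".")
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed fraction")
    return ax
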