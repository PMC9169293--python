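"""The predictor contract and its implementations.

Any model that can be fitted on survey respondents and return a mean
response (a probability for binary indicators, a real value for ratings)
for every individual plugs into the estimator.  Three implementations ship:

* :class:`NullPredictor` — predicts the survey mean everywhere; the
  baseline against which any model must improve.
* :class:`ReferenceGBT` — the from-scratch gradient boosted trees of
  :mod:`saeboost.boosting`.
* :class:`XGBoostPredictor` — thin adapter over the xgboost library for
  production-scale runs; satisfies the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boosting import GBTConfig, GBTModel, boost, select_rounds_by_cv


class Predictor:
    """Fit-on-survey / predict-mean contract.

    ``handles_missing`` declares whether NaN feature values are accepted at
    fit/predict time; ``native_categorical`` whether integer level codes are
    understood (otherwise the design should be one-hot encoded).
    """

    handles_missing: bool = True
    native_categorical: bool = False

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "Predictor":
        raise NotImplementedError

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


class NullPredictor(Predictor):
    """Predicts the training mean for every individual, so every region
    receives the same estimate."""

    def __init__(self) -> None:
        self.mean_: float | None = None

    def fit(self, X, y) -> "NullPredictor":
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("cannot fit the null model on an empty survey")
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("predictor not fitted")
        return np.full(len(X), self.mean_)


def fit_null(responses) -> NullPredictor:
    """Fit the null model directly from a response vector."""
    model = NullPredictor()
    model.fit(None if responses is None else np.empty((len(responses), 0)), responses)
    return model


@dataclass
class ReferenceGBT(Predictor):
    """The package's own gradient boosted trees behind the contract.

    ``categorical_columns`` marks design columns holding level codes; they
    are split one-vs-rest.  With ``config.early_stopping`` the number of
    rounds is chosen by cross-validation before the final full-data refit.
    """

    config: GBTConfig = None
    categorical_columns: tuple[str, ...] = ()

    handles_missing = True
    native_categorical = True

    def __post_init__(self) -> None:
        if self.config is None:
            self.config = GBTConfig()
        self.model_: GBTModel | None = None
        self.columns_: list[str] | None = None
        self.n_rounds_: int | None = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        if self.columns_ is not None:
            X = X[self.columns_]
        return X.to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "ReferenceGBT":
        self.columns_ = list(X.columns)
        cat = np.array([c in self.categorical_columns for c in self.columns_])
        mat = self._matrix(X)
        y = np.asarray(y, dtype=float)
        config = self.config
        if config.early_stopping:
            t_star, _ = select_rounds_by_cv(mat, y, config, cat)
            self.n_rounds_ = t_star
            config = replace(config, n_rounds=t_star, early_stopping=False)
        else:
            self.n_rounds_ = config.n_rounds
        self.model_ = boost(mat, y, config, cat)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("predictor not fitted")
        return self.model_.predict(self._matrix(X))


@dataclass
class XGBoostPredictor(Predictor):
    """Adapter over the xgboost library.

    ``loss`` selects the objective (``logistic`` -> ``binary:logistic``,
    ``squared`` -> ``reg:squarederror``).  Missing values are handled
    natively; categorical design columns should be one-hot encoded.
    Regularization defaults differ from the reference implementation, so
    predictions agree approximately, not exactly.
    """

    loss: str = "logistic"
    learning_rate: float = 0.3
    n_rounds: int = 50
    max_depth: int = 6
    seed: int = 0
    n_jobs: int = 1

    handles_missing = True
    native_categorical = False

    def __post_init__(self) -> None:
        self.model_ = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "XGBoostPredictor":
        import xgboost as xgb

        common = dict(
            n_estimators=self.n_rounds,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            random_state=self.seed,
            n_jobs=self.n_jobs,
            tree_method="hist",
        )
        if self.loss == "logistic":
            self.model_ = xgb.XGBClassifier(objective="binary:logistic", **common)
        else:
            self.model_ = xgb.XGBRegressor(objective="reg:squarederror", **common)
        self.model_.fit(X.to_numpy(dtype=float), np.asarray(y))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("predictor not fitted")
        mat = X.to_numpy(dtype=float)
        if self.loss == "logistic":
            return self.model_.predict_proba(mat)[:, 1].astype(float)
        return self.model_.predict(mat).astype(float)


def make_predictor(name: str, loss: str = "logistic", seed: int = 0, **kw) -> Predictor:
    """Factory by name: ``null``, ``gbt-ref`` or ``gbt-lib``."""
    if name == "null":
        return NullPredictor()
    if name == "gbt-ref":
        config = GBTConfig(loss=loss, seed=seed, **kw)
        return ReferenceGBT(config=config)
    if name == "gbt-lib":
        return XGBoostPredictor(loss=loss, seed=seed, **kw)
    raise ValueError(f"unknown model {name!r}")
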