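"""Unit-level small area estimation.

The estimator combines observed survey responses with model predictions for
everyone else,

    y*_i = y_i          if i is a respondent,
           f(x_i)       otherwise,

aggregates y* to region means p_r = (1/|R_r|) sum_{i in R_r} y*_i at any
level of the nested geography, and attaches model-agnostic bootstrap
percentile prediction intervals: resample the respondents with replacement,
refit f, simulate the unknown outcomes from the refitted model (Bernoulli
for binary indicators; Normal with the residual variance sigma^2 for
ratings) while holding the observed outcomes fixed — a finite-sample
correction that shrinks the intervals to zero width as survey coverage
approaches a census — and take percentiles of the replicate region means.

The public surface is statsmodels-like: build a :class:`SmallAreaModel`
from a :class:`~saeboost.population.PopulationFrame`, call ``fit()``, and
read estimates, intervals and diagnostics off the returned
:class:`SmallAreaResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import OGCConfig, build_design, sequential_impute
from .population import PopulationFrame, level_codes
from .predictors import Predictor, XGBoostPredictor, fit_null  # noqa: F401 (re-export)

logger = logging.getLogger(__name__)

LEVELS_DEFAULT = ("neighborhood", "district", "municipality", "national")


@dataclass
class BootstrapConfig:
    """Bootstrap interval settings: B replicates (default 200 — stable 95%
    percentiles at tractable cost), nominal coverage level, seed."""

    n_replicates: int = 200
    nominal_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.nominal_level < 1.0:
            raise ValueError("nominal level must be in (0,1)")


# ---------------------------------------------------------------------------
# elemental operations


def combine_predicted_responses(
    pop: PopulationFrame, model: Predictor, X: pd.DataFrame, outcome: str = "binary"
) -> np.ndarray:
    """The combined response y*: observed where surveyed, model mean
    elsewhere (a probability, not a hard label, for binary outcomes)."""
    surveyed = pop.survey_mask
    y_star = pop.data["response"].to_numpy(dtype=float).copy()
    if (~surveyed).any():
        preds = np.asarray(model.predict(X.loc[~surveyed]), dtype=float)
        bad = np.isnan(preds)
        if bad.any():
            rows = pop.data.index[~surveyed][bad][:5].tolist()
            raise ValueError(f"model could not score unsurveyed rows {rows}")
        if outcome == "binary":
            preds = _clamp_unit(preds, "combined response")
        y_star[~surveyed] = preds
    if np.isnan(y_star).any():
        raise ValueError("combined response still has absent values")
    return y_star


def _clamp_unit(p: np.ndarray, what: str) -> np.ndarray:
    if (p < 0).any() or (p > 1).any():
        logger.warning("%s outside [0,1]; clamping", what)
        return np.clip(p, 0.0, 1.0)
    return p


def aggregate_regions(
    y_star: np.ndarray,
    pop: PopulationFrame,
    level: str,
    nominal_level: float = 0.95,
) -> pd.DataFrame:
    """Point estimates p_r: the plain average of y* per region at ``level``,
    with population and respondent counts."""
    codes = level_codes(pop.data, level)
    if codes.isna().any():
        raise ValueError(f"individual(s) without a region code at level {level!r}")
    df = pd.DataFrame(
        {
            "region_code": codes.to_numpy(),
            "y_star": np.asarray(y_star, dtype=float),
            "surveyed": pop.survey_mask.astype(int),
        }
    )
    grouped = df.groupby("region_code", sort=True).agg(
        n_population=("y_star", "size"),
        n_respondents=("surveyed", "sum"),
        estimate=("y_star", "mean"),
    )
    out = grouped.reset_index()
    out.insert(0, "level", level)
    out["nominal_level"] = nominal_level
    return out


def direct_estimates(pop: PopulationFrame, level: str) -> pd.DataFrame:
    """The direct (respondents-only) estimator; NaN for regions without a
    single respondent."""
    codes = level_codes(pop.data, level)
    resp = pop.survey_mask
    df = pd.DataFrame(
        {
            "region_code": codes.to_numpy(),
            "response": pop.data["response"].to_numpy(dtype=float),
            "surveyed": resp.astype(int),
        }
    )
    grouped = df.groupby("region_code", sort=True).agg(
        n_population=("response", "size"),
        n_respondents=("surveyed", "sum"),
    )
    means = (
        df[resp].groupby("region_code")["response"].mean()
        if resp.any()
        else pd.Series(dtype=float)
    )
    grouped["estimate"] = means.reindex(grouped.index)
    out = grouped.reset_index()
    out.insert(0, "level", level)
    return out


def residual_variance(y_obs: np.ndarray, f_bar: np.ndarray) -> float:
    """sigma^2 = (1/|I|) sum_i (y_i - fbar(x_i))^2 over respondents, where
    fbar is the across-replicate mean bootstrap prediction."""
    y_obs = np.asarray(y_obs, dtype=float)
    f_bar = np.asarray(f_bar, dtype=float)
    if y_obs.size == 0:
        raise ValueError("residual variance needs at least one respondent")
    if y_obs.shape != f_bar.shape:
        raise ValueError("responses and predictions length mismatch")
    return float(np.mean((y_obs - f_bar) ** 2))


def bootstrap_prediction_intervals(
    pop: PopulationFrame,
    X: pd.DataFrame,
    model_factory: Callable[[int], Predictor],
    levels: Sequence[str],
    outcome: str,
    config: BootstrapConfig,
    estimates: dict[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], float | None]:
    """Percentile prediction intervals for the region means at each level.

    For b = 1..B: resample the respondents with replacement (same size),
    fit f^(b) via ``model_factory``, and predict the unsurveyed rows.  For
    ratings, sigma^2 is computed once from the across-replicate mean
    prediction on respondents.  Each replicate then simulates unsurveyed
    outcomes independently — Bernoulli(f^(b)(x_i)) or
    Normal(f^(b)(x_i), sigma^2) — keeps observed outcomes fixed, and records
    the replicate region means p_r^(b); bounds are the empirical
    (1±level)/2 percentiles (linear interpolation between order statistics).

    Returns ``(tables, sigma2)``: per-level estimate tables with ``lower``
    and ``upper`` columns, and sigma^2 (None for binary outcomes).
    """
    if pop.n_respondents < 2:
        raise ValueError("bootstrap needs at least 2 respondents")
    B = config.n_replicates
    rng = np.random.default_rng(config.seed)
    surveyed = pop.survey_mask
    resp_idx = np.flatnonzero(surveyed)
    unsv_idx = np.flatnonzero(~surveyed)
    y_obs = pop.data["response"].to_numpy(dtype=float)[resp_idx]
    n_resp, n_unsv = resp_idx.size, unsv_idx.size

    preds_unsv = np.empty((B, n_unsv))
    preds_resp = np.empty((B, n_resp)) if outcome != "binary" else None
    X_unsv = X.iloc[unsv_idx]
    X_resp = X.iloc[resp_idx]
    for b in range(B):
        draw = rng.integers(0, n_resp, n_resp)
        fit_seed = int(rng.integers(2**31 - 1))
        model = model_factory(fit_seed)
        model.fit(X_resp.iloc[draw], y_obs[draw])
        if n_unsv:
            p = np.asarray(model.predict(X_unsv), dtype=float)
            preds_unsv[b] = _clamp_unit(p, "bootstrap prediction") if outcome == "binary" else p
        if preds_resp is not None:
            preds_resp[b] = np.asarray(model.predict(X_resp), dtype=float)

    sigma2 = None
    if n_unsv:
        if outcome == "binary":
            y_sim = (rng.random((B, n_unsv)) < preds_unsv).astype(float)
        else:
            sigma2 = residual_variance(y_obs, preds_resp.mean(axis=0))
            y_sim = preds_unsv + rng.normal(0.0, np.sqrt(sigma2), size=(B, n_unsv))
    else:
        y_sim = np.empty((B, 0))
        if outcome != "binary":
            sigma2 = residual_variance(y_obs, preds_resp.mean(axis=0))

    lo_q = (1.0 - config.nominal_level) / 2.0
    hi_q = 1.0 - lo_q
    tables: dict[str, pd.DataFrame] = {}
    for level in levels:
        codes = level_codes(pop.data, level)
        region_index = pd.Index(np.unique(codes), name="region_code")
        pos = region_index.get_indexer(codes)
        n_regions = len(region_index)
        counts = np.bincount(pos, minlength=n_regions).astype(float)
        fixed = np.bincount(pos[resp_idx], weights=y_obs, minlength=n_regions)
        pos_unsv = pos[unsv_idx]
        p_b = np.empty((B, n_regions))
        for b in range(B):
            sums = np.bincount(pos_unsv, weights=y_sim[b], minlength=n_regions)
            p_b[b] = (fixed + sums) / counts
        lower, upper = np.quantile(p_b, [lo_q, hi_q], axis=0)
        if level not in estimates:
            raise KeyError(f"no point-estimate table supplied for level {level!r}")
        table = estimates[level].copy()
        table = table.set_index("region_code").loc[region_index].reset_index()
        table["lower"] = lower
        table["upper"] = upper
        table["nominal_level"] = config.nominal_level
        tables[level] = table[
            [
                "level",
                "region_code",
                "n_population",
                "n_respondents",
                "estimate",
                "lower",
                "upper",
                "nominal_level",
            ]
        ]
        if outcome == "binary":
            vals = table[["estimate", "lower", "upper"]].to_numpy()
            if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
                logger.warning("binary estimates outside [0,1] at level %s", level)
    return tables, sigma2


# ---------------------------------------------------------------------------
# model / results


class SmallAreaModel:
    """Unit-level small area estimation model.

    Parameters
    ----------
    population
        The registry + survey table (respondents carry responses).
    predictor_factory
        ``callable(seed) -> Predictor``; defaults to the xgboost adapter
        with boosting defaults for the outcome type.
    outcome
        ``"binary"`` (prevalence) or ``"continuous"`` (average rating).
    spatial_mode
        ``"xy"`` (raw coordinates) or ``"ogc"`` (oblique projections).
    impute
        Apply sequential random-forest imputation before model fitting (for
        predictors that cannot accept missing values).
    """

    def __init__(
        self,
        population: PopulationFrame,
        predictor_factory: Callable[[int], Predictor] | None = None,
        outcome: str = "binary",
        spatial_mode: str = "xy",
        ogc: OGCConfig | None = None,
        impute: bool = False,
        seed: int = 0,
    ) -> None:
        if outcome not in ("binary", "continuous"):
            raise ValueError(f"unknown outcome kind {outcome!r}")
        if population.n_respondents < 1:
            raise ValueError("population has no respondents to fit on")
        population.validate()
        self.population = population
        self.outcome = outcome
        self.spatial_mode = spatial_mode
        self.ogc = ogc or OGCConfig()
        self.impute = impute
        self.seed = seed
        if predictor_factory is None:
            loss = "logistic" if outcome == "binary" else "squared"
            predictor_factory = lambda s: XGBoostPredictor(loss=loss, seed=s)  # noqa: E731
        self.predictor_factory = predictor_factory

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SmallAreaModel":
        return cls(PopulationFrame(data), **kwargs)

    def _design(self) -> pd.DataFrame:
        pop = self.population
        if self.impute:
            pop = sequential_impute(pop, seed=self.seed)
            self._imputed = pop
        probe = self.predictor_factory(self.seed)
        encoding = "codes" if probe.native_categorical else "onehot"
        X, schema = build_design(
            pop, spatial_mode=self.spatial_mode, ogc=self.ogc,
            categorical_encoding=encoding,
        )
        self.design_schema_ = schema
        return X

    def fit(
        self,
        levels: Sequence[str] = LEVELS_DEFAULT,
        bootstrap: BootstrapConfig | None = None,
    ) -> "SmallAreaResults":
        """Fit the predictor on respondents, combine, aggregate, and (if a
        bootstrap config is given) attach prediction intervals."""
        pop = self.population
        X = self._design()
        predictor = self.predictor_factory(self.seed)
        predictor.fit(X.loc[pop.survey_mask], pop.responses)
        y_star = combine_predicted_responses(pop, predictor, X, self.outcome)
        nominal = bootstrap.nominal_level if bootstrap else 0.95
        estimates = {
            level: aggregate_regions(y_star, pop, level, nominal) for level in levels
        }
        direct = {level: direct_estimates(pop, level) for level in levels}
        sigma2 = None
        if bootstrap is not None:
            estimates, sigma2 = bootstrap_prediction_intervals(
                pop, X, self.predictor_factory, levels, self.outcome, bootstrap,
                estimates=estimates,
            )
        return SmallAreaResults(
            model=self,
            predictor=predictor,
            y_star=y_star,
            estimate_tables=estimates,
            direct_tables=direct,
            sigma2=sigma2,
            bootstrap=bootstrap,
            levels=tuple(levels),
        )


@dataclass
class SmallAreaResults:
    """Fitted estimates: point estimates (and intervals) per level, the
    combined response, the fitted predictor and diagnostics."""

    model: SmallAreaModel
    predictor: Predictor
    y_star: np.ndarray
    estimate_tables: dict[str, pd.DataFrame]
    direct_tables: dict[str, pd.DataFrame]
    sigma2: float | None
    bootstrap: BootstrapConfig | None
    levels: tuple[str, ...] = field(default_factory=tuple)

    def estimates(self, level: str) -> pd.DataFrame:
        if level not in self.estimate_tables:
            raise KeyError(f"level {level!r} was not estimated")
        return self.estimate_tables[level]

    def direct(self, level: str) -> pd.DataFrame:
        return self.direct_tables[level]

    @property
    def national_estimate(self) -> float:
        return float(np.mean(self.y_star))

    def summary(self) -> str:
        pop = self.model.population
        lines = [
            "Small Area Estimation Results",
            "=" * 46,
            f"outcome:            {self.model.outcome}",
            f"population size:    {len(pop)}",
            f"respondents:        {pop.n_respondents}",
            f"spatial mode:       {self.model.spatial_mode}",
            f"national estimate:  {self.national_estimate:.4f}",
        ]
        if self.sigma2 is not None:
            lines.append(f"residual variance:  {self.sigma2:.4f}")
        if self.bootstrap is not None:
            lines.append(
                f"intervals:          {self.bootstrap.nominal_level:.0%} percentile,"
                f" B={self.bootstrap.n_replicates}"
            )
        lines.append("-" * 46)
        for level in self.levels:
            t = self.estimate_tables[level]
            row = f"{level:<14} {len(t):>5} regions  mean p_r {t['estimate'].mean():.4f}"
            if "lower" in t.columns:
                width = (t["upper"] - t["lower"]).mean()
                row += f"  mean width {width:.4f}"
            lines.append(row)
        return "\n".join(lines)
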