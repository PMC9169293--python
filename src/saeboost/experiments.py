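"""Simulation studies on synthetic populations.

Each study generates populations from the synthetic module, runs the
estimator, and measures a property against the known truth: interval
coverage, small-neighborhood parameter recovery, and correction of
survey-inclusion bias.  They are used by the acceptance script and the test
suite, and are runnable directly for exploration.

Problem sizes default to the package's reference study conditions: 20,000
individuals in 100 neighborhoods with a 10% survey (~2,000 respondents) and
B=200 bootstrap replicates.
"""

from __future__ import annotations

import numpy as np

from .model import BootstrapConfig, SmallAreaModel, direct_estimates
from .population import PopulationFrame
from .predictors import Predictor, XGBoostPredictor
from .synthetic import (
    PopulationConfig,
    SurveyDesign,
    default_surface,
    generate_population,
    sample_survey,
    true_region_means,
)


def _default_factory(seed: int) -> Predictor:
    # a compact, well-calibrated classifier for the smooth default surface
    return XGBoostPredictor(loss="logistic", n_rounds=30, max_depth=3, seed=seed)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def coverage_study(
    seed: int = 0,
    n_replicates: int = 10,
    n_individuals: int = 20_000,
    survey_fraction: float = 0.1,
    n_bootstrap: int = 200,
    nominal_level: float = 0.95,
    predictor_factory=None,
) -> dict:
    """Empirical coverage of the bootstrap percentile prediction intervals.

    For each simulation replicate: draw a population with the default
    logistic outcome surface, take a simple random survey, run the interval
    procedure at neighborhood level, and check whether the realized
    finite-population prevalence of each neighborhood (the census mean of
    the realized outcomes) lies inside its interval.  Returns the coverage
    over all neighborhood-by-replicate cases, in percent.
    """
    factory = predictor_factory or _default_factory
    seeds = _child_seeds(seed, 3 * n_replicates).reshape(n_replicates, 3)
    hits = 0
    cases = 0
    for rep in range(n_replicates):
        s_pop, s_svy, s_boot = (int(s) for s in seeds[rep])
        config = PopulationConfig(n_individuals=n_individuals, seed=s_pop)
        census, _ = generate_population(config, default_surface())
        pop = sample_survey(census, SurveyDesign(survey_fraction, seed=s_svy))
        model = SmallAreaModel(
            pop, predictor_factory=factory, outcome="binary", spatial_mode="ogc"
        )
        res = model.fit(
            levels=("neighborhood",),
            bootstrap=BootstrapConfig(
                n_replicates=n_bootstrap, nominal_level=nominal_level, seed=s_boot
            ),
        )
        table = res.estimates("neighborhood")
        realized = census.data.groupby("region_nbhd")["response"].mean()
        realized = realized.loc[table["region_code"]].to_numpy()
        inside = (table["lower"].to_numpy() <= realized) & (
            realized <= table["upper"].to_numpy()
        )
        hits += int(inside.sum())
        cases += len(inside)
    return {
        "coverage_pct": 100.0 * hits / cases,
        "n_cases": cases,
        "nominal_pct": 100.0 * nominal_level,
    }


def recovery_study(
    seed: int = 0,
    n_individuals: int = 20_000,
    survey_fraction: float = 0.1,
    small_region_max_respondents: int = 15,
    predictor_factory=None,
) -> dict:
    """Neighborhood-level RMSE against the true region means: model-based
    versus direct (respondents-only), among neighborhoods with fewer than
    ``small_region_max_respondents`` respondents."""
    factory = predictor_factory or _default_factory
    s_pop, s_svy, s_fit = (int(s) for s in _child_seeds(seed, 3))
    config = PopulationConfig(n_individuals=n_individuals, seed=s_pop)
    census, mu = generate_population(config, default_surface())
    pop = sample_survey(census, SurveyDesign(survey_fraction, seed=s_svy))

    model = SmallAreaModel(
        pop, predictor_factory=factory, outcome="binary", spatial_mode="ogc", seed=s_fit
    )
    res = model.fit(levels=("neighborhood",))
    est = res.estimates("neighborhood").set_index("region_code")
    direct = direct_estimates(pop, "neighborhood").set_index("region_code")
    truth = true_region_means(mu, pop.hierarchy, "neighborhood").set_index("region")

    small = est.index[est["n_respondents"] < small_region_max_respondents]
    small = [r for r in small if not np.isnan(direct.loc[r, "estimate"])]
    t = truth.loc[small, "true_mean"].to_numpy()
    rmse_model = float(np.sqrt(np.mean((est.loc[small, "estimate"].to_numpy() - t) ** 2)))
    rmse_direct = float(np.sqrt(np.mean((direct.loc[small, "estimate"].to_numpy() - t) ** 2)))
    return {
        "n_small_regions": len(small),
        "rmse_model": rmse_model,
        "rmse_direct": rmse_direct,
    }


def bias_correction_study(
    seed: int = 0,
    n_replicates: int = 20,
    n_individuals: int = 10_000,
    survey_fraction: float = 0.1,
    bias_feature: str = "income_pct",
    bias_strength: float = 1.0,
    predictor_factory=None,
) -> dict:
    """Income-biased survey inclusion: does the model-based national
    estimate beat the raw respondent mean?

    Inclusion probability rises with income, income raises the outcome, so
    the respondent mean is biased upward; the model sees every individual's
    registry income and can undo the imbalance.  Counts the replicates in
    which |model estimate - truth| < |respondent mean - truth|, truth being
    the realized census mean.
    """
    factory = predictor_factory or _default_factory
    seeds = _child_seeds(seed, 3 * n_replicates).reshape(n_replicates, 3)
    wins = 0
    for rep in range(n_replicates):
        s_pop, s_svy, s_fit = (int(s) for s in seeds[rep])
        config = PopulationConfig(n_individuals=n_individuals, seed=s_pop)
        census, _ = generate_population(config, default_surface())
        design = SurveyDesign(
            survey_fraction, bias_feature=bias_feature,
            bias_strength=bias_strength, seed=s_svy,
        )
        pop = sample_survey(census, design)
        truth = float(census.data["response"].mean())
        raw = float(pop.responses.mean())
        model = SmallAreaModel(
            pop, predictor_factory=factory, outcome="binary", spatial_mode="ogc",
            seed=s_fit,
        )
        res = model.fit(levels=("national",))
        est = float(res.estimates("national")["estimate"].iloc[0])
        if abs(est - truth) < abs(raw - truth):
            wins += 1
    return {"wins": wins, "n_replicates": n_replicates}
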