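import numpy as np
import pandas as pd
import pytest

from saeboost.population import PopulationFrame
from saeboost.synthetic import (
    PopulationConfig,
    SurveyDesign,
    default_surface,
    generate_population,
    sample_survey,
)


def make_frame(
    features: dict,
    categorical: list[str] | None = None,
    response=None,
    survey_flag=None,
    n_neighborhoods: int = 2,
    coords=None,
) -> PopulationFrame:
    """Build a minimal population frame from feature arrays for unit tests.

    Individuals are dealt round-robin into ``n_neighborhoods`` neighborhoods
    inside one district of one municipality unless region columns are passed
    explicitly inside ``features``.
    """
    n = len(next(iter(features.values())))
    rng = np.random.default_rng(0)
    data = {
        "id": np.arange(n),
        "x_coord_m": coords[0] if coords else rng.uniform(0, 1000, n),
        "y_coord_m": coords[1] if coords else rng.uniform(0, 1000, n),
        "survey_flag": np.ones(n, dtype=int) if survey_flag is None else np.asarray(survey_flag),
        "response": np.zeros(n) if response is None else np.asarray(response, dtype=float),
    }
    if "region_nbhd" not in features:
        nb = np.arange(n) % n_neighborhoods
        data["region_nbhd"] = [f"M01-D01-N{i + 1:03d}" for i in nb]
        data["region_district"] = "M01-D01"
        data["region_muni"] = "M01"
    df = pd.DataFrame(data)
    feature_cols = []
    for name, vals in features.items():
        df[name] = vals
        if not name.startswith("region_"):
            feature_cols.append(name)
    return PopulationFrame(df, feature_cols, categorical or [])


@pytest.fixture(scope="session")
def small_census():
    """A 6,000-person census with the default schema and logistic surface,
    plus the true individual means."""
    config = PopulationConfig(n_individuals=6_000, seed=101)
    return generate_population(config, default_surface())


@pytest.fixture(scope="session")
def small_survey(small_census):
    """The census above with a 15% simple random survey drawn."""
    census, _ = small_census
    return sample_survey(census, SurveyDesign(0.15, seed=202))
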