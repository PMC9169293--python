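"""Synthetic population generator.

Emulates the structure of a national person registry joined to a health
survey: categorical demographics and household variables with realistic
missingness, home coordinates in meters, a neighborhood -> district ->
municipality nesting, a known outcome surface (logistic prevalence or
Gaussian rating) with nonlinear, interaction and smooth spatial components,
and a survey subsample with optional inclusion bias.

Because the real microdata live in a restricted remote-access environment,
everything downstream (feature engineering, boosting, region estimation,
validation) is developed and tested against populations drawn here, where
the true individual means -- and hence the true and realized region means --
are known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .population import PopulationFrame, RegionHierarchy, level_codes


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FeatureSpec:
    """One feature of the synthetic registry.

    kind ``categorical``: ``levels`` and ``probabilities`` (summing to 1).
    kind ``continuous``: ``distribution`` is a dict understood by
    :func:`_draw_continuous` (``uniform``, ``normal`` with optional
    truncation, ``randint``) — kept declarative so configs serialize.
    ``per_neighborhood`` draws one value per neighborhood and broadcasts it
    (e.g. address density).
    """

    name: str
    kind: str
    levels: Sequence[str] | None = None
    probabilities: Sequence[float] | None = None
    distribution: dict | None = None
    per_neighborhood: bool = False

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels or self.probabilities is None:
                raise ValueError(f"categorical feature {self.name!r} needs levels+probabilities")
            if len(self.levels) != len(self.probabilities):
                raise ValueError(f"{self.name!r}: levels/probabilities length mismatch")
            if not math.isclose(sum(self.probabilities), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.name!r}: probabilities must sum to 1")
        elif self.kind == "continuous":
            if self.distribution is None:
                raise ValueError(f"continuous feature {self.name!r} needs a distribution")
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class PopulationConfig:
    """Size, geography, feature schema and missingness of a synthetic
    population.

    The default geography is 5 municipalities x 2 districts x 10
    neighborhoods = 100 neighborhoods over a 100 km square; neighborhood
    populations are drawn from a Dirichlet so sizes vary the way real
    neighborhoods do.
    """

    n_individuals: int = 20_000
    n_municipalities: int = 5
    n_districts_per: int = 2
    n_neighborhoods_per: int = 10
    feature_schema: list[FeatureSpec] = field(default_factory=lambda: default_schema())
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    coordinate_extent: tuple[float, float, float, float] = (0.0, 100_000.0, 0.0, 100_000.0)
    size_concentration: float = 3.0  # Dirichlet alpha for neighborhood sizes
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (
            self.n_individuals,
            self.n_municipalities,
            self.n_districts_per,
            self.n_neighborhoods_per,
        ):
            if n < 1:
                raise ValueError("population and region counts must be >= 1")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0,1]")

    @property
    def n_neighborhoods(self) -> int:
        return self.n_municipalities * self.n_districts_per * self.n_neighborhoods_per


# Reduced-cardinality registry schema: individual-level demographics,
# household variables and a neighborhood-level address density.
def default_schema() -> list[FeatureSpec]:
    return [
        FeatureSpec("age", "continuous",
                    distribution={"dist": "normal", "mean": 50, "sd": 18, "min": 18, "max": 105}),
        FeatureSpec("sex", "categorical", ["male", "female"], [0.5, 0.5]),
        FeatureSpec("ethnicity", "categorical",
                    ["netherlands", "morocco", "turkey", "suriname", "antilles",
                     "other_nonwestern", "other_western"],
                    [0.76, 0.02, 0.02, 0.02, 0.01, 0.07, 0.10]),
        FeatureSpec("marital_status", "categorical",
                    ["single", "married", "divorced", "widowed"],
                    [0.35, 0.45, 0.12, 0.08]),
        FeatureSpec("education", "categorical",
                    ["basis", "vmbo_bk", "vmbo_gt", "mbo23", "mbo4",
                     "havo_vwo", "hbo_wo_bach", "hbo_wo_master"],
                    [0.08, 0.09, 0.09, 0.18, 0.18, 0.10, 0.18, 0.10]),
        FeatureSpec("household_type", "categorical",
                    ["single", "couple_no_children", "couple_children",
                     "single_parent", "other"],
                    [0.30, 0.28, 0.30, 0.08, 0.04]),
        FeatureSpec("household_size", "continuous",
                    distribution={"dist": "randint", "low": 1, "high": 8}),
        FeatureSpec("income_source", "categorical",
                    ["wage", "self_employed", "benefit", "pension", "other"],
                    [0.52, 0.10, 0.10, 0.24, 0.04]),
        FeatureSpec("home_ownership", "categorical",
                    ["owner", "rental_no_allowance", "rental_allowance"],
                    [0.57, 0.28, 0.15]),
        FeatureSpec("income_pct", "continuous",
                    distribution={"dist": "uniform", "low": 1, "high": 100}),
        FeatureSpec("assets_pct", "continuous",
                    distribution={"dist": "uniform", "low": 1, "high": 100}),
        FeatureSpec("address_density", "continuous", per_neighborhood=True,
                    distribution={"dist": "uniform", "low": 1, "high": 100}),
    ]


# Per-feature missingness fractions mirroring the registry: education is by
# far the most incomplete variable (37.8%), household economics ~2%.
DEFAULT_MISSINGNESS = {
    "marital_status": 0.006,
    "education": 0.378,
    "income_source": 0.024,
    "home_ownership": 0.020,
    "income_pct": 0.024,
    "assets_pct": 0.024,
}


@dataclass
class SpatialField:
    """Smooth scalar field over the map used as the spatial component of the
    outcome surface: amplitude * sin(2πx/λ + φx) * cos(2πy/λ + φy)."""

    amplitude: float = 0.0
    wavelength: float = 60_000.0
    phase_x: float = 0.3
    phase_y: float = 0.8

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.zeros_like(np.asarray(x, dtype=float))
        w = 2.0 * np.pi / self.wavelength
        return self.amplitude * np.sin(w * x + self.phase_x) * np.cos(w * y + self.phase_y)


@dataclass
class InteractionTerm:
    """coef * t(a) * t(b) where a token is a numeric feature name or
    ``"feature=level"`` for a categorical indicator; numeric tokens are
    centered."""

    a: str
    b: str
    coef: float
    center_a: float = 0.0
    center_b: float = 0.0


@dataclass
class TrueSurface:
    """The known true outcome surface mu_i = link(eta_i).

    eta = intercept + Σ linear + Σ quadratic + Σ categorical effects
        + Σ interactions + spatial(x, y).

    ``linear``/``quadratic`` map a continuous feature to ``(coef, center)``;
    ``categorical`` maps a feature to per-level offsets.  ``link`` is
    ``"logistic"`` (binary outcome, Bernoulli draw) or ``"identity"``
    (rating, Gaussian draw with ``noise_sd``).
    """

    intercept: float = 0.0
    linear: dict[str, tuple[float, float]] = field(default_factory=dict)
    quadratic: dict[str, tuple[float, float]] = field(default_factory=dict)
    categorical: dict[str, dict[str, float]] = field(default_factory=dict)
    interactions: list[InteractionTerm] = field(default_factory=list)
    spatial: SpatialField | Callable | None = None
    link: str = "logistic"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "identity" and self.noise_sd <= 0:
            raise ValueError("identity link requires noise_sd > 0")

    # -- evaluation ---------------------------------------------------------

    def _token(self, data: pd.DataFrame, token: str, center: float) -> np.ndarray:
        if "=" in token:
            feat, level = token.split("=", 1)
            self._check(data, feat)
            return (data[feat].to_numpy(dtype=object) == level).astype(float)
        self._check(data, token)
        return data[token].to_numpy(dtype=float) - center

    @staticmethod
    def _check(data: pd.DataFrame, feat: str) -> None:
        if feat not in data.columns:
            raise KeyError(f"surface references unknown feature {feat!r}")

    def linear_predictor(self, data: pd.DataFrame, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        eta = np.full(len(data), self.intercept, dtype=float)
        for feat, (coef, center) in self.linear.items():
            self._check(data, feat)
            eta += coef * (data[feat].to_numpy(dtype=float) - center)
        for feat, (coef, center) in self.quadratic.items():
            self._check(data, feat)
            eta += coef * (data[feat].to_numpy(dtype=float) - center) ** 2
        for feat, effects in self.categorical.items():
            self._check(data, feat)
            vals = data[feat].to_numpy(dtype=object)
            eta += np.array([effects.get(v, 0.0) for v in vals])
        for term in self.interactions:
            eta += term.coef * self._token(data, term.a, term.center_a) * self._token(
                data, term.b, term.center_b
            )
        if self.spatial is not None:
            eta += np.asarray(self.spatial(x, y), dtype=float)
        return eta

    def true_means(self, data: pd.DataFrame, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(data, x, y)
        if self.link == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def default_surface(link: str = "logistic") -> TrueSurface:
    """Moderate, learnable outcome surface: age and income effects with a
    curvature term, education/sex offsets, a sex-by-income interaction and a
    smooth spatial wave (~±0.6 on the linear scale)."""
    surface = TrueSurface(
        intercept=-0.9,
        linear={"age": (0.016, 50.0), "income_pct": (0.008, 50.0)},
        quadratic={"age": (-0.0005, 50.0)},
        categorical={
            "education": {
                "basis": -0.30, "vmbo_bk": -0.20, "vmbo_gt": -0.15,
                "mbo23": -0.05, "mbo4": 0.0, "havo_vwo": 0.10,
                "hbo_wo_bach": 0.20, "hbo_wo_master": 0.30,
            },
            "sex": {"female": 0.20},
        },
        interactions=[InteractionTerm("sex=female", "income_pct", 0.004, center_b=50.0)],
        spatial=SpatialField(amplitude=0.6, wavelength=60_000.0),
        link=link,
    )
    if link == "identity":
        # rating-style outcome around 6 on a 0-10 scale
        surface.intercept = 6.0
        surface.noise_sd = 1.0
    return surface


@dataclass
class SurveyDesign:
    """Survey inclusion design: simple Bernoulli(fraction) sampling, with an
    optional monotone inclusion bias on a named feature (positive strength
    makes high values of the feature more likely to respond)."""

    sampling_fraction: float = 0.1
    bias_feature: str | None = None
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# generation


def _draw_continuous(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    kind = dist["dist"]
    if kind == "uniform":
        return rng.uniform(dist["low"], dist["high"], size)
    if kind == "normal":
        vals = rng.normal(dist["mean"], dist["sd"], size)
        return np.clip(vals, dist.get("min", -np.inf), dist.get("max", np.inf))
    if kind == "randint":
        return rng.integers(dist["low"], dist["high"] + 1, size).astype(float)
    raise ValueError(f"unknown distribution {kind!r}")


def generate_hierarchy(config: PopulationConfig, rng: np.random.Generator | None = None) -> RegionHierarchy:
    """Assign every individual to a neighborhood nested in a district nested
    in a municipality, and lay the neighborhoods out as tiles of the map.

    Neighborhoods occupy cells of a near-square grid covering the coordinate
    extent, in row-major order, so the neighborhoods of one district (and the
    districts of one municipality) are spatially contiguous blocks.
    Neighborhood populations are multinomial with Dirichlet-distributed
    weights, so region sizes vary.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_nbhd = config.n_neighborhoods
    codes = []
    for m in range(config.n_municipalities):
        for d in range(config.n_districts_per):
            for b in range(config.n_neighborhoods_per):
                codes.append(
                    (
                        f"M{m + 1:02d}",
                        f"M{m + 1:02d}-D{d + 1:02d}",
                        f"M{m + 1:02d}-D{d + 1:02d}-N{b + 1:03d}",
                    )
                )
    muni, district, nbhd = map(np.array, zip(*codes))

    if config.n_individuals < n_nbhd:
        raise ValueError("need at least one individual per neighborhood")
    # every neighborhood is inhabited; the remainder is spread with
    # Dirichlet-multinomial weights so sizes vary like real neighborhoods
    weights = rng.dirichlet(np.full(n_nbhd, config.size_concentration))
    sizes = 1 + rng.multinomial(config.n_individuals - n_nbhd, weights)
    assignment = np.repeat(np.arange(n_nbhd), sizes)

    x0, x1, y0, y1 = config.coordinate_extent
    gx = int(np.ceil(np.sqrt(n_nbhd)))
    gy = int(np.ceil(n_nbhd / gx))
    dx, dy = (x1 - x0) / gx, (y1 - y0) / gy
    cell = np.arange(n_nbhd)
    cx, cy = cell % gx, cell // gx
    tiles = pd.DataFrame(
        {
            "region_nbhd": nbhd,
            "x0": x0 + cx * dx,
            "x1": x0 + (cx + 1) * dx,
            "y0": y0 + cy * dy,
            "y1": y0 + (cy + 1) * dy,
        }
    )

    frame = pd.DataFrame(
        {
            "region_nbhd": nbhd[assignment],
            "region_district": district[assignment],
            "region_muni": muni[assignment],
        }
    )
    return RegionHierarchy(frame, tiles=tiles)


def generate_population(
    config: PopulationConfig,
    surface: TrueSurface,
    hierarchy: RegionHierarchy | None = None,
) -> tuple[PopulationFrame, np.ndarray]:
    """Draw a full census population with realized outcomes.

    Returns the population (``survey_flag`` = 1 and ``response`` observed for
    everyone — a census; apply :func:`sample_survey` for a survey draw) and
    the vector of true individual means mu_i.

    The outcome surface is evaluated on the complete latent feature values;
    missingness is masked in afterwards, emulating registry incompleteness
    that hides, but does not alter, the truth.
    """
    if not config.feature_schema:
        raise ValueError("feature schema is empty")
    rng = np.random.default_rng(config.seed)
    if hierarchy is None:
        hierarchy = generate_hierarchy(config, rng)
    n = hierarchy.n_individuals

    # coordinates uniform within each neighborhood's tile
    tiles = hierarchy.tiles.set_index("region_nbhd")
    nb = hierarchy.frame["region_nbhd"]
    t = tiles.loc[nb].reset_index(drop=True)
    x = rng.uniform(t["x0"].to_numpy(), t["x1"].to_numpy())
    y = rng.uniform(t["y0"].to_numpy(), t["y1"].to_numpy())

    data = pd.DataFrame(index=range(n))
    categorical = []
    for spec in config.feature_schema:
        if spec.kind == "categorical":
            vals = rng.choice(np.array(spec.levels, dtype=object), size=n, p=spec.probabilities)
            data[spec.name] = pd.Series(vals, dtype="object")
            categorical.append(spec.name)
        elif spec.per_neighborhood:
            per_nbhd = _draw_continuous(rng, spec.distribution, len(tiles))
            lookup = pd.Series(per_nbhd, index=tiles.index)
            data[spec.name] = lookup.loc[nb].to_numpy()
        else:
            data[spec.name] = _draw_continuous(rng, spec.distribution, n)

    mu = surface.true_means(data, x, y)
    if surface.link == "logistic":
        if np.any((mu <= 0) | (mu >= 1)):
            raise ValueError("logistic surface produced means outside (0,1)")
        response = rng.binomial(1, mu).astype(float)
    else:
        response = rng.normal(mu, surface.noise_sd)

    # MCAR masking per feature
    for name, rate in config.missingness_rates.items():
        if name not in data.columns:
            raise KeyError(f"missingness rate for unknown feature {name!r}")
        if rate > 0:
            mask = rng.random(n) < rate
            if name in categorical:
                col = data[name].to_numpy(dtype=object)
                col[mask] = None
                data[name] = pd.Series(col, dtype="object")
            else:
                data.loc[mask, name] = np.nan

    out = pd.DataFrame(
        {
            "id": np.arange(n),
            "region_nbhd": hierarchy.frame["region_nbhd"].to_numpy(),
            "region_district": hierarchy.frame["region_district"].to_numpy(),
            "region_muni": hierarchy.frame["region_muni"].to_numpy(),
            "x_coord_m": x,
            "y_coord_m": y,
            "survey_flag": np.ones(n, dtype=int),
            "response": response,
        }
    )
    for c in data.columns:
        out[c] = data[c]
    frame = PopulationFrame(out, list(data.columns), categorical)
    return frame, mu


def sample_survey(pop: PopulationFrame, design: SurveyDesign) -> PopulationFrame:
    """Draw survey membership; non-respondents lose their response.

    With ``bias_feature`` set, the inclusion probability is
    sigmoid(logit(fraction) + strength * z) where z is the standardized
    feature (missing -> 0), i.e. monotone in the feature.
    """
    rng = np.random.default_rng(design.seed)
    n = len(pop)
    f = design.sampling_fraction
    if f >= 1.0:
        probs = np.ones(n)
    elif design.bias_feature is None or design.bias_strength == 0.0:
        probs = np.full(n, f)
    else:
        vals = pop.data[design.bias_feature].to_numpy(dtype=float)
        z = np.where(np.isnan(vals), 0.0, vals)
        z = (z - np.nanmean(z)) / (np.nanstd(z) + 1e-12)
        logit = np.log(f / (1 - f)) + design.bias_strength * z
        probs = 1.0 / (1.0 + np.exp(-logit))
    flags = (rng.random(n) < probs).astype(int)
    out = pop.copy()
    out.data["survey_flag"] = flags
    out.data.loc[flags == 0, "response"] = np.nan
    return out


def true_region_means(
    true_means: np.ndarray, hierarchy: RegionHierarchy | pd.DataFrame, level: str
) -> pd.DataFrame:
    """Arithmetic mean of true individual means per region at ``level``."""
    frame = hierarchy.frame if isinstance(hierarchy, RegionHierarchy) else hierarchy
    if len(true_means) != len(frame):
        raise ValueError("true_means length does not match hierarchy")
    codes = level_codes(frame, level)
    grouped = (
        pd.DataFrame({"region": codes.to_numpy(), "mu": np.asarray(true_means, float)})
        .groupby("region", sort=True)["mu"]
        .mean()
    )
    return grouped.rename("true_mean").reset_index()
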