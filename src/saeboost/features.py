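"""Deterministic feature engineering.

Three jobs: the oblique geographic coordinate (OGC) transform, assembly of a
model-ready design table from a population frame, and the sequential
random-forest imputation used when a downstream model cannot accept missing
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .population import PopulationFrame

logger = logging.getLogger(__name__)


@dataclass
class OGCConfig:
    """Oblique geographic coordinates: project (x, y) onto ``n_angles``
    equally spaced directions theta_k = pi(k-1)/K, k = 1..K, in [0, pi).

    Axis-aligned tree splits on the projections give the model access to
    oblique spatial boundaries and suppress orthogonal map artifacts.  K=24
    is a good accuracy/size trade-off for country-scale maps.
    """

    n_angles: int = 24
    include_raw_xy: bool = False

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")

    @property
    def angles(self) -> np.ndarray:
        k = np.arange(1, self.n_angles + 1)
        return np.pi * (k - 1) / self.n_angles


def ogc_transform(x, y, config: OGCConfig) -> np.ndarray:
    """Oblique coordinates of one or many points.

    Computes sqrt(x² + y²) · cos[theta_k − atan2(y, x)], the quadrant-safe
    form of the polar projection; algebraically this equals
    x·cos(theta_k) + y·sin(theta_k).  The origin maps to all zeros (the
    limit of the projection) and is logged.

    Returns an array of shape (n, K), or (K,) for scalar input.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if not (np.isfinite(x_arr).all() and np.isfinite(y_arr).all()):
        raise ValueError("coordinates must be finite")
    r = np.hypot(x_arr, y_arr)
    phi = np.arctan2(y_arr, x_arr)
    if np.any(r == 0):
        logger.warning("OGC transform at the origin: returning zeros")
    theta = config.angles
    out = r[:, None] * np.cos(theta[None, :] - phi[:, None])
    out[r == 0] = 0.0
    if np.isscalar(x) or np.ndim(x) == 0:
        return out[0]
    return out


def build_design(
    frame: PopulationFrame,
    spatial_mode: str = "xy",
    ogc: OGCConfig | None = None,
    categorical_encoding: str = "codes",
) -> tuple[pd.DataFrame, dict]:
    """Assemble the model-ready feature table.

    Parameters
    ----------
    spatial_mode
        ``"xy"`` keeps the raw coordinates; ``"ogc"`` appends the K oblique
        projections (raw coordinates kept only if ``ogc.include_raw_xy``).
    categorical_encoding
        ``"codes"`` passes each categorical as integer level codes (NaN for
        missing) for predictors with native categorical splits; ``"onehot"``
        emits full-rank indicator columns (first level dropped; a missing
        original value makes the whole indicator block NaN, preserving
        missingness).

    Returns the design DataFrame (row-aligned with the population) and a
    schema dict with ``columns``, ``categorical`` (design columns that are
    level codes) and ``levels`` (original level order per encoded feature).
    """
    if spatial_mode not in ("xy", "ogc"):
        raise ValueError(f"unknown spatial_mode {spatial_mode!r}")
    if categorical_encoding not in ("codes", "onehot"):
        raise ValueError(f"unknown categorical_encoding {categorical_encoding!r}")

    data = frame.data
    cols: dict[str, np.ndarray] = {}
    categorical_cols: list[str] = []
    levels: dict[str, list[str]] = {}
    for name in frame.feature_columns:
        if name in frame.categorical_columns:
            cat = pd.Categorical(data[name])
            levels[name] = [str(v) for v in cat.categories]
            if categorical_encoding == "codes":
                codes = cat.codes.astype(float)
                codes[codes < 0] = np.nan
                cols[name] = codes
                categorical_cols.append(name)
            else:
                missing = cat.codes < 0
                for lev in cat.categories[1:]:
                    ind = (cat == lev).astype(float)
                    ind[missing] = np.nan
                    cols[f"{name}={lev}"] = ind
        else:
            cols[name] = data[name].to_numpy(dtype=float)

    x = data["x_coord_m"].to_numpy(dtype=float)
    y = data["y_coord_m"].to_numpy(dtype=float)
    if spatial_mode == "xy":
        cols["x_coord_m"] = x
        cols["y_coord_m"] = y
    else:
        ogc = ogc or OGCConfig()
        if ogc.include_raw_xy:
            cols["x_coord_m"] = x
            cols["y_coord_m"] = y
        proj = ogc_transform(x, y, ogc)
        for k in range(ogc.n_angles):
            cols[f"ogc_{k + 1:02d}"] = proj[:, k]

    design = pd.DataFrame(cols, index=data.index)
    schema = {
        "columns": list(design.columns),
        "categorical": categorical_cols,
        "levels": levels,
    }
    return design, schema


def imputation_order(frame: PopulationFrame) -> list[str]:
    """Features with missing values, in the order sequential imputation
    processes them: ascending missing fraction, ties by column position."""
    feats = frame.feature_columns
    frac = {c: frame.data[c].isna().mean() for c in feats}
    return sorted(
        (c for c in feats if frac[c] > 0.0),
        key=lambda c: (frac[c], feats.index(c)),
    )


def sequential_impute(
    frame: PopulationFrame, seed: int = 0, n_trees: int = 100
) -> PopulationFrame:
    """Fill every missing feature value by sequential random-forest
    prediction.

    Features are processed in ascending order of missing fraction (ties
    broken by column position).  For each incomplete feature a forest is
    fitted on the currently complete columns — originally complete features,
    coordinates, and features already imputed — using the rows where the
    feature is observed, then predicts the missing entries: classification
    for categoricals (majority vote), regression for continuous.  One pass;
    observed entries are never altered, so the operation is idempotent.
    """
    data = frame.data.copy()
    feats = frame.feature_columns
    missing_frac = {c: data[c].isna().mean() for c in feats}
    if any(v >= 1.0 for v in missing_frac.values()):
        worst = [c for c, v in missing_frac.items() if v >= 1.0]
        raise ValueError(f"feature(s) 100% missing, nothing to learn from: {worst}")

    complete = [c for c in feats if missing_frac[c] == 0.0]
    if not complete:
        raise ValueError("no fully observed feature to start imputation from")
    predictors = complete + ["x_coord_m", "y_coord_m"]

    order = imputation_order(frame)
    rng = np.random.default_rng(seed)
    for target in order:
        X = _numeric_matrix(data, predictors, frame.categorical_columns)
        obs = ~data[target].isna().to_numpy()
        fit_seed = int(rng.integers(2**31 - 1))
        if target in frame.categorical_columns:
            model = RandomForestClassifier(n_estimators=n_trees, random_state=fit_seed)
            yobs = data.loc[obs, target].to_numpy(dtype=object).astype(str)
            model.fit(X[obs], yobs)
            filled = model.predict(X[~obs])
            col = data[target].to_numpy(dtype=object)
            col[~obs] = filled
            data[target] = pd.Series(col, dtype="object")
        else:
            model = RandomForestRegressor(n_estimators=n_trees, random_state=fit_seed)
            model.fit(X[obs], data.loc[obs, target].to_numpy(dtype=float))
            vals = data[target].to_numpy(dtype=float)
            vals[~obs] = model.predict(X[~obs])
            data[target] = vals
        predictors.append(target)

    return PopulationFrame(data, list(frame.feature_columns), list(frame.categorical_columns))


def _numeric_matrix(data: pd.DataFrame, columns: list[str], categorical: list[str]) -> np.ndarray:
    """Complete columns as a numeric matrix: one-hot for categoricals."""
    parts = []
    for c in columns:
        if c in categorical:
            cat = pd.Categorical(data[c])
            parts.append((cat.codes[:, None] == np.arange(len(cat.categories))[None, :]).astype(float))
        else:
            parts.append(data[c].to_numpy(dtype=float)[:, None])
    return np.hstack(parts)
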