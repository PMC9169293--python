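"""File round-trips and run configuration.

All tables are UTF-8 delimited text: comma separator, dot decimal, empty
field = missing.  The population table has the documented mandatory columns
(id, region_nbhd, region_district, region_muni, x_coord_m, y_coord_m,
survey_flag, response) followed by the feature columns; estimates tables
have (level, region_code, n_population, n_respondents, estimate, lower,
upper, nominal_level).  Run configuration is a YAML key-value file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import MANDATORY_COLUMNS, PopulationFrame


def write_population_table(frame: PopulationFrame, path) -> None:
    cols = list(MANDATORY_COLUMNS) + frame.feature_columns
    out = frame.data[cols].copy()
    out.to_csv(path, index=False, na_rep="")


def read_population_table(path) -> PopulationFrame:
    """Read and validate a population table.

    Raises on a missing mandatory column, a survey flag outside {0,1}, or a
    respondent row with an empty response.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    if df["survey_flag"].isna().any() or not df["survey_flag"].isin([0, 1]).all():
        raise ValueError("survey_flag values outside {0,1}")
    frame = PopulationFrame(df)
    frame.validate()
    return frame


def write_estimates(tables: dict[str, pd.DataFrame], path) -> None:
    """Concatenate per-level estimate tables, sorted by level then region
    code, numbers at 6 significant digits for byte-stable diffs."""
    combined = pd.concat(tables.values(), ignore_index=True)
    combined = combined.sort_values(["level", "region_code"]).reset_index(drop=True)
    combined.to_csv(path, index=False, na_rep="", float_format="%.6g")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("level", "region_code", "n_population", "n_respondents", "estimate"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; see the README for the YAML
    layout.  Either ``input_path`` (an existing population table) or
    ``simulation`` (synthetic-population settings) must be set."""

    input_path: str | None = None
    simulation: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {"name": "gbt-lib", "loss": "logistic"})
    spatial_mode: str = "xy"
    ogc_k: int = 24
    include_raw_xy: bool = False
    impute: str = "none"
    levels: tuple = ("neighborhood", "district", "municipality", "national")
    bootstrap: dict | None = None
    validation: dict = field(default_factory=dict)
    output_dir: str = "saeboost_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_path is None and not self.simulation:
            raise ValueError("config needs either 'input' or 'simulation'")
        if self.impute not in ("none", "sequential"):
            raise ValueError(f"unknown impute mode {self.impute!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            input_path=d.get("input"),
            simulation=d.get("simulation", {}) or {},
            model=d.get("model", {"name": "gbt-lib", "loss": "logistic"}),
            spatial_mode=d.get("spatial_mode", "xy"),
            ogc_k=int(d.get("ogc_k", 24)),
            include_raw_xy=bool(d.get("include_raw_xy", False)),
            impute=d.get("impute", "none"),
            levels=tuple(d.get("levels", ("neighborhood", "district", "municipality", "national"))),
            bootstrap=d.get("bootstrap"),
            validation=d.get("validation", {}) or {},
            output_dir=d.get("output_dir", "saeboost_out"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "input": self.input_path,
            "simulation": self.simulation,
            "model": self.model,
            "spatial_mode": self.spatial_mode,
            "ogc_k": self.ogc_k,
            "include_raw_xy": self.include_raw_xy,
            "impute": self.impute,
            "levels": list(self.levels),
            "bootstrap": self.bootstrap,
            "validation": self.validation,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def seed_for(seed: int, stream: str) -> int:
    """Deterministic named substream seed below 2^31 so stages can be rerun
    independently of one another."""
    digest = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def write_manifest(path, config: RunConfig, outputs: list[str]) -> None:
    from . import __version__

    manifest = {
        "package": "saeboost",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "outputs": outputs,
        "seed_streams": {
            name: seed_for(config.seed, name)
            for name in ("simulation", "survey", "model", "cv", "bootstrap", "imputation")
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def simulation_from_config(sim: dict, seed: int):
    """Build (PopulationConfig, TrueSurface, SurveyDesign) from the
    'simulation' section of a run config; omitted keys use package
    defaults."""
    from .synthetic import (
        PopulationConfig,
        SurveyDesign,
        default_surface,
    )

    pop_kwargs = {
        k: sim[k]
        for k in (
            "n_individuals",
            "n_municipalities",
            "n_districts_per",
            "n_neighborhoods_per",
            "size_concentration",
        )
        if k in sim
    }
    if "missingness_rates" in sim:
        pop_kwargs["missingness_rates"] = dict(sim["missingness_rates"])
    config = PopulationConfig(seed=seed_for(seed, "simulation"), **pop_kwargs)

    link = sim.get("link", "logistic")
    surface = default_surface(link)
    if "noise_sd" in sim:
        surface.noise_sd = float(sim["noise_sd"])
    if "intercept" in sim:
        surface.intercept = float(sim["intercept"])

    survey = sim.get("survey", {}) or {}
    design = SurveyDesign(
        sampling_fraction=float(survey.get("fraction", 0.1)),
        bias_feature=survey.get("bias_feature"),
        bias_strength=float(survey.get("bias_strength", 0.0)),
        seed=seed_for(seed, "survey"),
    )
    return config, surface, design
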