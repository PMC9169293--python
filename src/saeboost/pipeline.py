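"""End-to-end orchestration: population (read or simulated) -> model ->
region estimates (+ intervals) -> validation reports, all written to an
output directory with a machine-readable run manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import OGCConfig
from .io import (
    RunConfig,
    read_population_table,
    seed_for,
    simulation_from_config,
    write_estimates,
    write_manifest,
    write_population_table,
)
from .model import BootstrapConfig, SmallAreaModel
from .predictors import make_predictor
from .synthetic import generate_population, sample_survey
from .validation import (
    calibration_bins,
    compute_metrics,
    kfold_oos_predictions,
    roc_points,
)

logger = logging.getLogger(__name__)


def predictor_factory_from_config(model_cfg: dict, outcome: str):
    """Build a seeded predictor factory from the 'model' config section."""
    name = model_cfg.get("name", "gbt-lib")
    loss = model_cfg.get("loss", "logistic" if outcome == "binary" else "squared")
    kwargs = {}
    if name == "gbt-ref":
        for src, dst in (
            ("alpha", "learning_rate"),
            ("rounds", "n_rounds"),
            ("max_depth", "max_depth"),
            ("min_leaf_size", "min_leaf_size"),
            ("early_stopping", "early_stopping"),
            ("cv_folds", "cv_folds"),
        ):
            if src in model_cfg:
                kwargs[dst] = model_cfg[src]
    elif name == "gbt-lib":
        for src, dst in (
            ("alpha", "learning_rate"),
            ("rounds", "n_rounds"),
            ("max_depth", "max_depth"),
        ):
            if src in model_cfg:
                kwargs[dst] = model_cfg[src]
    return lambda seed: make_predictor(name, loss=loss, seed=seed, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full run; returns a dict of written artifact paths."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    # --- population ---------------------------------------------------------
    if config.input_path is not None:
        logger.info("stage=read input=%s", config.input_path)
        pop = read_population_table(config.input_path)
    else:
        logger.info("stage=simulate seed_stream=%d", seed_for(config.seed, "simulation"))
        pop_config, surface, design = simulation_from_config(config.simulation, config.seed)
        census, _ = generate_population(pop_config, surface)
        pop = sample_survey(census, design)
        pop_path = out_dir / "population.csv"
        write_population_table(pop, pop_path)
        outputs.append(str(pop_path))

    outcome = config.model.get("outcome", "binary")

    # --- model + estimation -------------------------------------------------
    factory = predictor_factory_from_config(config.model, outcome)
    bootstrap = None
    if config.bootstrap:
        bootstrap = BootstrapConfig(
            n_replicates=int(config.bootstrap.get("replicates", 200)),
            nominal_level=float(config.bootstrap.get("nominal", 0.95)),
            seed=seed_for(config.seed, "bootstrap"),
        )
    model = SmallAreaModel(
        pop,
        predictor_factory=factory,
        outcome=outcome,
        spatial_mode=config.spatial_mode,
        ogc=OGCConfig(n_angles=config.ogc_k, include_raw_xy=config.include_raw_xy),
        impute=(config.impute == "sequential"),
        seed=seed_for(config.seed, "model"),
    )
    logger.info("stage=estimate levels=%s bootstrap=%s", config.levels, bool(bootstrap))
    results = model.fit(levels=config.levels, bootstrap=bootstrap)
    est_path = out_dir / "estimates.csv"
    write_estimates(results.estimate_tables, est_path)
    outputs.append(str(est_path))
    direct_path = out_dir / "direct_estimates.csv"
    write_estimates(results.direct_tables, direct_path)
    outputs.append(str(direct_path))
    (out_dir / "summary.txt").write_text(results.summary() + "\n")
    outputs.append(str(out_dir / "summary.txt"))

    # --- validation ---------------------------------------------------------
    if config.validation.get("enabled", False):
        folds = int(config.validation.get("folds", 5))
        X = model._design()
        resp_mask = pop.survey_mask
        y = pop.responses
        logger.info("stage=validate folds=%d", folds)
        oos = kfold_oos_predictions(
            X.loc[resp_mask], y, factory, k=folds, seed=seed_for(config.seed, "cv")
        )
        report = compute_metrics(y, np.clip(oos, 0, 1) if outcome == "binary" else oos)
        metrics_path = out_dir / "metrics.csv"
        pd.DataFrame([report.to_dict()]).to_csv(metrics_path, index=False, float_format="%.6g")
        outputs.append(str(metrics_path))
        if outcome == "binary":
            roc = roc_points(y, np.clip(oos, 0, 1), int(config.validation.get("thresholds", 100)))
            roc.to_csv(out_dir / "roc.csv", index=False, float_format="%.6g")
            outputs.append(str(out_dir / "roc.csv"))
            cal = calibration_bins(y, np.clip(oos, 0, 1), int(config.validation.get("bins", 100)))
            cal.to_csv(out_dir / "calibration.csv", index=False, float_format="%.6g")
            outputs.append(str(out_dir / "calibration.csv"))

    manifest_path = out_dir / "manifest.json"
    write_manifest(manifest_path, config, outputs)
    outputs.append(str(manifest_path))
    return {"outputs": outputs, "results": results}
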