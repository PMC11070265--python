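"""End-to-end orchestration: simulate -> prep -> tune -> fit -> evaluate
-> importance -> map -> irreplace, with a provenance manifest.

Every stage reads and writes files under the run's output directory, so
stages are individually re-runnable from the CLI and a finished run is
fully described by its config, seeds and the manifest hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geotiff import read_geotiff
from .irreplace import irreplaceability_map
from .jsdm import Hyperparameters, JSDMModel
from .maps import composition_map, filter_species_by_auc, predict_raster, richness_map
from .synthcommunity import (
    SpeciesResponseSpec,
    extract_site_covariates,
    generate_landscape,
    generate_species,
    make_design,
    simulate_incidence,
)
from .tables import (
    CovariateTable,
    IncidenceMatrix,
    call_presences,
    filter_by_incidence,
    read_coverage_table,
    reduce_covariates_vif,
    split_train_test,
)
from .tune import SearchSpace, final_evaluation, kfold_cv, sample_candidates
from .xai import interaction_importance, permutation_importance, summarize_importance

logger = logging.getLogger(__name__)

__all__ = ["default_config", "demo_config", "load_config", "validate_inputs", "run_pipeline"]

STAGES = ["simulate", "prep", "tune", "fit", "evaluate", "importance", "map", "irreplace"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        "grid_shape": [32, 32],
        "n_covariates": 6,
        "autocorr_range": 4.0,
        "pixel_size": 30.0,
        "n_species": 12,
        "latent_rank": 2,
        "sparsity": 0.2,
        "n_points": 89,
        "paired_fraction": 0.36,
    },
    "inputs": {"incidence_csv": None, "coverage_csv": None, "covariates_csv": None,
               "raster": None},
    "prep": {
        "min_coverage_fraction": 0.5,
        "min_incidence": 6,
        "vif_threshold": 10.0,
        "train_fraction": 0.75,
        "group_by_point": False,
    },
    "tune": {
        "n_candidates": 20,
        "k": 5,
        "max_rank": 3,
        "epochs": 200,
        "mc_draws": 50,
        "hidden_options": [[], [25, 25]],
    },
    "importance": {"n_repeats": 10, "interactions": True, "grid_size": 10},
    "map": {
        "min_auc": 0.7,
        "fallback_all_species": True,
        "richness_threshold": 0.5,
        "tsne_perplexity": 30.0,
        "tsne_max_pixels": 10000,
    },
    "irreplace": {"fraction": 0.5, "block_size": 1, "max_units": 20000},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def demo_config() -> dict:
    """Desk-scale demo: 32x32 grid, 12 species, 6 covariates, 20 candidates."""
    cfg = default_config()
    cfg["map"]["min_auc"] = 0.5
    return cfg


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def validate_inputs(Y: IncidenceMatrix | None, X: CovariateTable | None, stack=None) -> list[dict]:
    """Schema/coordinate sanity report; entries carry severity levels."""
    report: list[dict] = []

    def err(msg):
        report.append({"severity": "error", "message": msg})

    def warn(msg):
        report.append({"severity": "warning", "message": msg})

    if Y is not None:
        bad = set(np.unique(Y.values)) - {0, 1}
        if bad:
            err(f"non-binary incidence values: {sorted(bad)}")
        if Y.x is None or Y.y is None:
            warn("incidence matrix carries no coordinates")
    if Y is not None and X is not None:
        if Y.n_samples != X.n_samples:
            err(f"sample counts differ: incidence {Y.n_samples}, covariates {X.n_samples}")
        elif list(Y.sample_ids) != list(X.sample_ids):
            err("sample id order differs between incidence and covariate tables")
    if X is not None and stack is not None:
        missing = [c for c in X.covariate_names if c not in stack.band_names]
        extra = [b for b in stack.band_names if b not in X.covariate_names]
        for name in missing:
            err(f"raster is missing covariate band {name!r}")
        for name in extra:
            warn(f"raster band {name!r} not present in the covariate table")
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, out: Path) -> None:
    sc = cfg["simulate"]
    seed = int(cfg["seed"])
    landscape = generate_landscape(
        tuple(sc["grid_shape"]), sc["n_covariates"], sc["autocorr_range"],
        seed=seed, pixel_size=sc["pixel_size"],
    )
    spec = generate_species(
        landscape, sc["n_species"], sc["latent_rank"], sc["sparsity"], seed=seed + 1
    )
    design = make_design(landscape, sc["n_points"], sc["paired_fraction"], seed=seed + 2)
    Y = simulate_incidence(spec, landscape, design, seed=seed + 3)
    X = extract_site_covariates(landscape, design)
    from .geotiff import write_geotiff

    write_geotiff(out / "landscape.tif", landscape.to_raster_stack())
    Y.to_csv(out / "incidence.csv")
    X.to_csv(out / "site_covariates.csv")
    (out / "species_spec.json").write_text(json.dumps(spec.to_dict(), sort_keys=True))


def _load_prep_inputs(cfg: dict, out: Path) -> tuple[IncidenceMatrix, CovariateTable]:
    inputs = cfg.get("inputs", {})
    if cfg["simulate"]["enabled"]:
        Y = IncidenceMatrix.from_csv(out / "incidence.csv")
        X = CovariateTable.from_csv(out / "site_covariates.csv")
        return Y, X
    if inputs.get("coverage_csv"):
        coverage = read_coverage_table(inputs["coverage_csv"])
        Y = call_presences(coverage, cfg["prep"]["min_coverage_fraction"])
    elif inputs.get("incidence_csv"):
        Y = IncidenceMatrix.from_csv(inputs["incidence_csv"])
    else:
        raise FileNotFoundError("no incidence or coverage input configured")
    if not inputs.get("covariates_csv"):
        raise FileNotFoundError("no covariate table configured")
    X = CovariateTable.from_csv(inputs["covariates_csv"])
    return Y, X


def stage_prep(cfg: dict, out: Path) -> None:
    pc = cfg["prep"]
    Y, X = _load_prep_inputs(cfg, out)
    report = validate_inputs(Y, X)
    (out / "validation_report.json").write_text(json.dumps(report, indent=1))
    errors = [r for r in report if r["severity"] == "error"]
    if errors:
        raise ValueError(f"input validation failed: {errors[0]['message']}")
    Y = filter_by_incidence(Y, pc["min_incidence"])
    X_reduced, vif_log = reduce_covariates_vif(X, pc["vif_threshold"])
    vif_log.to_csv(out / "vif_removal_log.csv", index=False)
    split = split_train_test(
        Y, X_reduced, pc["train_fraction"], seed=int(cfg["seed"]) + 10,
        group_by_point=pc["group_by_point"],
    )
    Y.to_csv(out / "incidence_filtered.csv")
    X_reduced.to_csv(out / "covariates_reduced.csv")
    partition = pd.DataFrame(
        {
            "sample_id": Y.sample_ids,
            "partition": ["train" if i in set(split.train_idx) else "test"
                          for i in range(Y.n_samples)],
        }
    )
    partition.to_csv(out / "split.csv", index=False)


def _load_split(out: Path):
    Y = IncidenceMatrix.from_csv(out / "incidence_filtered.csv")
    X = CovariateTable.from_csv(out / "covariates_reduced.csv")
    part = pd.read_csv(out / "split.csv")
    train_idx = np.flatnonzero((part["partition"] == "train").to_numpy())
    test_idx = np.flatnonzero((part["partition"] == "test").to_numpy())
    return (
        Y.subset_samples(train_idx),
        X.subset_samples(train_idx),
        Y.subset_samples(test_idx),
        X.subset_samples(test_idx),
    )


def stage_tune(cfg: dict, out: Path) -> None:
    tc = cfg["tune"]
    Y_train, X_train, _, _ = _load_split(out)
    space = SearchSpace(
        {
            "env_penalty": ("log", 1e-4, 1.0),
            "env_mix": ("uniform", 0.0, 1.0),
            "trend_penalty": ("log", 1e-4, 1.0),
            "trend_mix": ("uniform", 0.0, 1.0),
            "loading_penalty": ("log", 1e-4, 1.0),
            "loading_mix": ("uniform", 0.0, 1.0),
            "latent_rank": ("choice", list(range(tc["max_rank"] + 1))),
            "hidden": ("choice", [list(h) for h in tc["hidden_options"]]),
            "lr": ("log", 0.01, 0.1),
            "epochs": ("fixed", tc["epochs"]),
            "mc_draws": ("fixed", tc["mc_draws"]),
        }
    )
    candidates = sample_candidates(space, n=tc["n_candidates"], seed=int(cfg["seed"]) + 20)
    cv = kfold_cv(Y_train, X_train, candidates, k=tc["k"], seed=int(cfg["seed"]) + 21)
    cv.table.to_csv(out / "cv_results.csv", index=False)
    best = cv.best_hyper.to_dict()
    with open(out / "best_hyper.yaml", "w") as fh:
        yaml.safe_dump(best, fh, sort_keys=True)


def _load_best_hyper(out: Path) -> Hyperparameters:
    with open(out / "best_hyper.yaml") as fh:
        return Hyperparameters.from_dict(yaml.safe_load(fh))


def stage_fit(cfg: dict, out: Path) -> None:
    from .jsdm import fit

    Y_train, X_train, _, _ = _load_split(out)
    hyper = _load_best_hyper(out)
    model = fit(Y_train, X_train, hyper=hyper, seed=int(cfg["seed"]) + 30)
    model.save(out / "model.jsdm")
    pd.DataFrame({"epoch": range(len(model.training_log)), "loss": model.training_log}).to_csv(
        out / "training_log.csv", index=False
    )


def stage_evaluate(cfg: dict, out: Path) -> None:
    Y_train, X_train, Y_test, X_test = _load_split(out)
    hyper = _load_best_hyper(out)
    result = final_evaluation(Y_train, X_train, Y_test, X_test, hyper,
                              seed=int(cfg["seed"]) + 30)
    pd.DataFrame(
        {
            "species": result["species_ids"],
            "explanatory_auc": result["explanatory_auc"],
            "predictive_auc": result["predictive_auc"],
        }
    ).to_csv(out / "auc.csv", index=False)


def stage_importance(cfg: dict, out: Path) -> None:
    ic = cfg["importance"]
    Y_train, X_train, _, _ = _load_split(out)
    model = JSDMModel.load(out / "model.jsdm")
    imp = permutation_importance(
        model, X_train, Y_train, n_repeats=ic["n_repeats"], seed=int(cfg["seed"]) + 40
    )
    imp.to_csv(out / "importance.csv")
    inter = None
    if ic["interactions"]:
        inter = interaction_importance(model, X_train, coords=Y_train.coords,
                                       grid_size=ic["grid_size"])
        inter.to_csv(out / "interactions.csv")
    summary = summarize_importance(imp, inter)
    summary.to_csv(out / "importance_summary.csv")
    from .xai import plot_importance_summary

    plot_importance_summary(summary, out / "importance_summary.png")


def stage_map(cfg: dict, out: Path) -> None:
    mc = cfg["map"]
    stack = read_geotiff(out / "landscape.tif") if cfg["simulate"]["enabled"] else read_geotiff(
        cfg["inputs"]["raster"]
    )
    # restrict the stack to the covariates retained by VIF reduction
    X = CovariateTable.from_csv(out / "covariates_reduced.csv")
    idx = [stack.band_names.index(n) for n in X.covariate_names]
    stack.data = stack.data[idx]
    stack.band_names = list(X.covariate_names)
    model = JSDMModel.load(out / "model.jsdm")
    auc_df = pd.read_csv(out / "auc.csv")
    auc_by_species = dict(zip(auc_df["species"], auc_df["predictive_auc"]))
    retained = filter_species_by_auc(auc_by_species, mc["min_auc"])
    if not retained and mc["fallback_all_species"]:
        logger.warning("AUC filter retained no species; mapping all species instead")
        retained = list(model.species_ids)
    maps = predict_raster(model, stack).subset(retained)
    maps_dir = out / "maps"
    maps.write_geotiffs(maps_dir)
    richness_map(maps, mc["richness_threshold"]).write_geotiff(out / "richness.tif")
    comp = composition_map(
        maps,
        perplexity=mc["tsne_perplexity"],
        max_pixels=mc["tsne_max_pixels"],
        seed=int(cfg["seed"]) + 50,
    )
    comp.write_geotiffs(out)
    pd.Series(retained, name="species").to_csv(out / "retained_species.csv", index=False)


def stage_irreplace(cfg: dict, out: Path) -> None:
    rc = cfg["irreplace"]
    retained = pd.read_csv(out / "retained_species.csv")["species"].tolist()
    model = JSDMModel.load(out / "model.jsdm")
    stack = read_geotiff(out / "landscape.tif") if cfg["simulate"]["enabled"] else read_geotiff(
        cfg["inputs"]["raster"]
    )
    X = CovariateTable.from_csv(out / "covariates_reduced.csv")
    idx = [stack.band_names.index(n) for n in X.covariate_names]
    stack.data = stack.data[idx]
    stack.band_names = list(X.covariate_names)
    maps = predict_raster(model, stack).subset(retained)
    result = irreplaceability_map(
        maps, fraction=rc["fraction"], block_size=rc["block_size"], max_units=rc["max_units"]
    )
    result.write_geotiff(out / "irreplaceability.tif")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "tune": stage_tune,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "importance": stage_importance,
    "map": stage_map,
    "irreplace": stage_irreplace,
}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, output_dir) -> Path:
    """Run every stage and write a provenance manifest.

    Deterministic given the config: a rerun into a fresh directory
    produces byte-identical artifacts (the manifest records sha256 per
    file). Stage failures abort with the stage name; earlier artifacts
    are retained.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s != "simulate" or cfg["simulate"]["enabled"]]
    for stage in stages:
        start = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %-10s %6.1fs", stage, time.perf_counter() - start)
    hashes = {
        str(p.relative_to(out)): _hash_file(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "biodivmap",
        "version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "stages": stages,
        "files": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
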