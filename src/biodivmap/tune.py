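"""Random hyperparameter search, k-fold CV, holdout evaluation and the
whole-data variability protocol."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .jsdm import Hyperparameters, auc_per_species, fit
from .tables import CovariateTable, IncidenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpace",
    "CVResult",
    "default_search_space",
    "sample_candidates",
    "fold_indices",
    "kfold_cv",
    "final_evaluation",
    "variability_protocol",
]


@dataclass
class SearchSpace:
    """Bounds/choices per hyperparameter field.

    Each entry maps a :class:`Hyperparameters` field to one of
    ``("log", lo, hi)`` (log-uniform), ``("uniform", lo, hi)``,
    ``("choice", [options])`` or ``("fixed", value)``.
    """

    entries: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty search space")
        for name, entry in self.entries.items():
            kind = entry[0]
            if kind in ("log", "uniform"):
                lo, hi = entry[1], entry[2]
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise ValueError(f"bad bounds for {name}: {entry}")
                if kind == "log" and lo <= 0:
                    raise ValueError(f"log-uniform bounds must be positive: {name}")
            elif kind == "choice":
                if len(entry[1]) == 0:
                    raise ValueError(f"empty choice list for {name}")
            elif kind != "fixed":
                raise ValueError(f"unknown entry kind {kind!r} for {name}")

    def draw(self, rng: np.random.Generator) -> Hyperparameters:
        values = {}
        for name, entry in self.entries.items():
            kind = entry[0]
            if kind == "log":
                values[name] = float(np.exp(rng.uniform(np.log(entry[1]), np.log(entry[2]))))
            elif kind == "uniform":
                values[name] = float(rng.uniform(entry[1], entry[2]))
            elif kind == "choice":
                values[name] = entry[1][rng.integers(len(entry[1]))]
            else:
                values[name] = entry[1]
        return Hyperparameters.from_dict(values)


def default_search_space(
    max_rank: int = 4,
    hidden_options: tuple = ((), (25, 25)),
    epochs: int = 300,
    mc_draws: int = 50,
) -> SearchSpace:
    return SearchSpace(
        {
            "env_penalty": ("log", 1e-4, 1.0),
            "env_mix": ("uniform", 0.0, 1.0),
            "trend_penalty": ("log", 1e-4, 1.0),
            "trend_mix": ("uniform", 0.0, 1.0),
            "loading_penalty": ("log", 1e-4, 1.0),
            "loading_mix": ("uniform", 0.0, 1.0),
            "latent_rank": ("choice", list(range(max_rank + 1))),
            "hidden": ("choice", [list(h) for h in hidden_options]),
            "lr": ("log", 0.01, 0.1),
            "epochs": ("fixed", epochs),
            "mc_draws": ("fixed", mc_draws),
        }
    )


def sample_candidates(space: SearchSpace, n: int = 1000, seed: int = 0) -> list[Hyperparameters]:
    """Seeded i.i.d. draws from the search space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [space.draw(rng) for _ in range(n)]


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled contiguous folds; the first ``n % k`` folds get the extra sample."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    folds, start = [], 0
    for size in sizes:
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


@dataclass
class CVResult:
    table: pd.DataFrame  # candidate, fold, species, auc
    candidate_scores: pd.Series  # mean AUC per candidate (nan-aware)
    best_candidate: int
    candidates: list[Hyperparameters]
    failed: list[int] = field(default_factory=list)

    @property
    def best_hyper(self) -> Hyperparameters:
        return self.candidates[self.best_candidate]


def _score_candidate(
    Y: IncidenceMatrix,
    X: CovariateTable,
    hyper: Hyperparameters,
    folds: list[np.ndarray],
    seed: int,
) -> tuple[list[dict], bool]:
    """Fit on k-1 folds, AUC per species on the held fold. Returns rows, ok."""
    rows = []
    any_ok = False
    n = Y.n_samples
    for fold_id, held in enumerate(folds):
        keep = np.setdiff1d(np.arange(n), held)
        try:
            model = fit(Y.subset_samples(keep), X.subset_samples(keep), hyper=hyper, seed=seed)
        except RuntimeError as exc:  # divergence
            logger.warning("fold %d diverged: %s", fold_id, exc)
            for sp in Y.species_ids:
                rows.append({"fold": fold_id, "species": sp, "auc": np.nan})
            continue
        any_ok = True
        Y_held = Y.subset_samples(held)
        X_held = X.subset_samples(held)
        prob = model.predict_prob(X_held.values, Y_held.coords, X_held.covariate_names)
        aucs = auc_per_species(prob, Y_held.values)
        for sp, a in zip(Y.species_ids, aucs):
            rows.append({"fold": fold_id, "species": sp, "auc": a})
    return rows, any_ok


def kfold_cv(
    Y: IncidenceMatrix,
    X: CovariateTable,
    candidates: list[Hyperparameters],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Cross-validate every candidate on the training data only.

    Candidate score = mean over species of fold-mean AUC (species with
    single-class folds dropped from the mean).  Best candidate =
    argmax score; ties broken by smaller total penalty, then candidate
    order.  Candidates whose every fold diverges are excluded.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    folds = fold_indices(Y.n_samples, k, seed)
    all_rows = []
    failed = []
    scores = np.full(len(candidates), np.nan)
    for ci, hyper in enumerate(candidates):
        rows, ok = _score_candidate(Y, X, hyper, folds, seed)
        for row in rows:
            row["candidate"] = ci
        all_rows.extend(rows)
        if not ok:
            failed.append(ci)
            continue
        df = pd.DataFrame(rows)
        fold_means = df.groupby("fold")["auc"].mean()  # nan-aware per fold
        scores[ci] = float(fold_means.mean())
    if np.all(np.isnan(scores)):
        raise RuntimeError("every candidate failed cross-validation")
    best_score = np.nanmax(scores)
    tied = [
        ci
        for ci in range(len(candidates))
        if np.isfinite(scores[ci]) and scores[ci] >= best_score - 1e-12
    ]
    best = min(tied, key=lambda ci: (candidates[ci].total_penalty, ci))
    table = pd.DataFrame(all_rows, columns=["candidate", "fold", "species", "auc"])
    return CVResult(
        table=table,
        candidate_scores=pd.Series(scores, name="mean_auc"),
        best_candidate=best,
        candidates=list(candidates),
        failed=failed,
    )


def final_evaluation(
    Y_train: IncidenceMatrix,
    X_train: CovariateTable,
    Y_test: IncidenceMatrix,
    X_test: CovariateTable,
    hyper: Hyperparameters,
    seed: int = 0,
) -> dict:
    """Refit on all training data; explanatory AUC (train) and predictive AUC (test)."""
    overlap = set(Y_train.sample_ids) & set(Y_test.sample_ids)
    if overlap:
        raise ValueError(f"train/test partitions overlap: {sorted(overlap)[:5]}")
    model = fit(Y_train, X_train, hyper=hyper, seed=seed)
    prob_train = model.predict_prob(X_train.values, Y_train.coords, X_train.covariate_names)
    prob_test = model.predict_prob(X_test.values, Y_test.coords, X_test.covariate_names)
    explanatory = auc_per_species(prob_train, Y_train.values)
    predictive = auc_per_species(prob_test, Y_test.values)
    return {
        "model": model,
        "species_ids": list(Y_train.species_ids),
        "explanatory_auc": explanatory,
        "predictive_auc": predictive,
        "explanatory_mean": float(np.nanmean(explanatory)),
        "explanatory_median": float(np.nanmedian(explanatory)),
        "predictive_mean": float(np.nanmean(predictive)),
        "predictive_median": float(np.nanmedian(predictive)),
    }


def variability_protocol(
    Y: IncidenceMatrix,
    X: CovariateTable,
    space: SearchSpace,
    n_candidates: int = 20,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Tune on the whole dataset, then re-run k-fold CV at the chosen
    hyperparameters to get the fold-wise AUC spread per species.

    The result is flagged ``optimistic=True``: tuning saw all the data,
    so these AUCs overestimate true predictive performance — the spread,
    not the level, is the quantity of interest.
    """
    candidates = sample_candidates(space, n=n_candidates, seed=seed)
    cv = kfold_cv(Y, X, candidates, k=k, seed=seed)
    best = cv.best_hyper
    rows, _ = _score_candidate(Y, X, best, fold_indices(Y.n_samples, k, seed + 1), seed)
    table = pd.DataFrame(rows)
    spread = table.groupby("species")["auc"].agg(["mean", "std", "count"])
    return {
        "best_hyper": best,
        "tuning_cv": cv,
        "fold_table": table,
        "auc_spread": spread,
        "optimistic": True,
    }
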