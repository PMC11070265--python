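"""Model-agnostic explanation layer.

Permutation importance (drop in explanatory AUC when a covariate's
column is shuffled) and pairwise interaction strength (Friedman's H^2
from partial-dependence functions on the link scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jsdm import JSDMModel, auc_per_species

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceTable",
    "InteractionTable",
    "permutation_drop",
    "permutation_importance",
    "interaction_importance",
    "summarize_importance",
    "plot_importance_summary",
]


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


@dataclass
class ImportanceTable:
    """Species x covariate AUC-drop matrix plus baseline AUCs."""

    drops: np.ndarray  # (n_species, n_covariates)
    baseline_auc: np.ndarray  # (n_species,)
    species_ids: list[str]
    covariate_names: list[str]

    def top_covariate(self) -> pd.Series:
        """Most important covariate per species (nan-AUC species excluded)."""
        out = {}
        for j, sp in enumerate(self.species_ids):
            if np.isnan(self.baseline_auc[j]):
                continue
            out[sp] = self.covariate_names[int(np.nanargmax(self.drops[j]))]
        return pd.Series(out, name="top_covariate")

    def counts(self) -> pd.Series:
        """Number of species for which each covariate ranks first."""
        top = self.top_covariate()
        return top.value_counts().reindex(self.covariate_names, fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.drops, index=self.species_ids, columns=self.covariate_names)
        df.insert(0, "baseline_auc", self.baseline_auc)
        df.index.name = "species"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def permutation_drop(
    model: JSDMModel,
    X: np.ndarray,
    Y: np.ndarray,
    coords: np.ndarray,
    covariate: int,
    perm: np.ndarray,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Per-species AUC drop for one explicit row permutation of one column."""
    X = np.asarray(X, dtype=float)
    if baseline is None:
        baseline = auc_per_species(model.predict_prob(X, coords), Y)
    Xp = X.copy()
    Xp[:, covariate] = Xp[perm, covariate]
    permuted = auc_per_species(model.predict_prob(Xp, coords), Y)
    return baseline - permuted


def permutation_importance(
    model: JSDMModel,
    X,
    Y,
    coords: np.ndarray | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Average explanatory-AUC drop over ``n_repeats`` column shuffles.

    The permuted metric is explanatory (same-data) AUC; species whose
    labels are single-class get nan baselines and are skipped in the
    rankings.
    """
    covariate_names = getattr(X, "covariate_names", None)
    if covariate_names is None:
        covariate_names = list(model.covariate_names)
    species_ids = getattr(Y, "species_ids", None)
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    if coords is None and hasattr(Y, "coords"):
        coords = Y.coords
    Yv = np.asarray(getattr(Y, "values", Y))
    if species_ids is None:
        species_ids = list(model.species_ids)
    if list(covariate_names) != list(model.covariate_names):
        raise ValueError("covariate schema does not match the fitted model")
    rng = np.random.default_rng(seed)
    n, p = Xv.shape
    baseline = auc_per_species(model.predict_prob(Xv, coords), Yv)
    drops = np.zeros((len(species_ids), p))
    for k in range(p):
        acc = np.zeros(len(species_ids))
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            acc += permutation_drop(model, Xv, Yv, coords, k, perm, baseline=baseline)
        drops[:, k] = acc / n_repeats
    return ImportanceTable(
        drops=drops,
        baseline_auc=baseline,
        species_ids=list(species_ids),
        covariate_names=list(covariate_names),
    )


# ---------------------------------------------------------------------------
# Interaction importance (Friedman's H^2)
# ---------------------------------------------------------------------------


@dataclass
class InteractionTable:
    """Pairwise interaction strength per species, symmetric, in [0, 1]."""

    values: np.ndarray  # (n_pairs, n_species)
    pairs: list[tuple[str, str]]
    species_ids: list[str]

    def h(self, a: str, b: str) -> np.ndarray:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.values[self.pairs.index(key)]

    def strongest_pair(self) -> pd.Series:
        out = {}
        for j, sp in enumerate(self.species_ids):
            out[sp] = "x".join(self.pairs[int(np.argmax(self.values[:, j]))])
        return pd.Series(out, name="strongest_pair")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(["|".join(p) for p in self.pairs], name="pair")
        return pd.DataFrame(self.values, index=idx, columns=self.species_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _partial_dependence(predict, X, cols, grid_values):
    """Mean link-scale prediction with columns held at grid values.

    ``cols``/``grid_values`` are parallel; the grid is the cartesian
    product, returned as an array of shape grid_shape + (n_species,).
    """
    shapes = [len(g) for g in grid_values]
    first = predict(X)
    out = np.empty((*shapes, first.shape[1]))
    for flat_idx in range(int(np.prod(shapes))):
        idx = np.unravel_index(flat_idx, shapes)
        Xg = X.copy()
        for col, g, i in zip(cols, grid_values, idx):
            Xg[:, col] = g[i]
        out[idx] = predict(Xg).mean(axis=0)
    return out


def interaction_importance(
    model: JSDMModel,
    X,
    coords: np.ndarray | None = None,
    pairs: list[tuple[str, str]] | None = None,
    grid_size: int = 20,
    seed: int = 0,
) -> InteractionTable:
    """Friedman's H^2 per covariate pair per species.

    Partial dependence is evaluated on the latent (link) scale over a
    quantile grid, so a purely additive model scores exactly 0.  Values
    are normalized by the variance of the joint partial-dependence
    function and clipped to [0, 1]; H(a, b) = H(b, a) by construction.
    Constant covariates are skipped with a warning.
    """
    del seed  # quantile grid is deterministic; kept for interface stability
    covariate_names = getattr(X, "covariate_names", list(model.covariate_names))
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    name_to_col = {n: i for i, n in enumerate(covariate_names)}
    if pairs is None:
        pairs = [
            (covariate_names[i], covariate_names[j])
            for i in range(len(covariate_names))
            for j in range(i + 1, len(covariate_names))
        ]

    if coords is None:
        # trend contribution is additive in eta and cancels in H^2
        fixed_coords = np.tile(model.trend.coord_mean, (Xv.shape[0], 1))
    else:
        fixed_coords = np.asarray(coords, dtype=float)

    def predict(Xg):
        return model.linear_predictor(Xg, fixed_coords)

    qs = np.linspace(0.0, 1.0, grid_size)
    grids = {}
    for name, col in name_to_col.items():
        g = np.unique(np.quantile(Xv[:, col], qs))
        grids[name] = g

    kept_pairs: list[tuple[str, str]] = []
    rows = []
    pd1_cache: dict[str, np.ndarray] = {}
    for a, b in pairs:
        ga, gb = grids[a], grids[b]
        if len(ga) < 2 or len(gb) < 2:
            logger.warning("skipping pair (%s, %s): constant covariate", a, b)
            continue
        for name, g in ((a, ga), (b, gb)):
            if name not in pd1_cache:
                pd_ = _partial_dependence(predict, Xv, [name_to_col[name]], [g])
                pd1_cache[name] = pd_ - pd_.mean(axis=0)
        pd_a = pd1_cache[a]  # (ga, S), centred
        pd_b = pd1_cache[b]
        pd_ab = _partial_dependence(predict, Xv, [name_to_col[a], name_to_col[b]], [ga, gb])
        pd_ab = pd_ab - pd_ab.mean(axis=(0, 1))
        resid = pd_ab - pd_a[:, None, :] - pd_b[None, :, :]
        num = np.sum(resid**2, axis=(0, 1))
        den = np.sum(pd_ab**2, axis=(0, 1))
        h2 = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)
        rows.append(np.clip(h2, 0.0, 1.0))
        kept_pairs.append((a, b))
    values = np.asarray(rows) if rows else np.empty((0, model.n_species))
    return InteractionTable(values=values, pairs=kept_pairs, species_ids=list(model.species_ids))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_importance(
    importance: ImportanceTable, interactions: InteractionTable | None = None
) -> pd.DataFrame:
    """Covariate ranking: species counts for which it is most important."""
    if not importance.species_ids:
        raise ValueError("empty importance table")
    summary = importance.counts().rename("n_species_top").to_frame()
    summary.index.name = "covariate"
    if interactions is not None and interactions.pairs:
        inter_counts = dict.fromkeys(summary.index, 0)
        for pair in interactions.strongest_pair():
            for name in pair.split("x"):
                if name in inter_counts:
                    inter_counts[name] += 1
        summary["n_species_top_interaction"] = pd.Series(inter_counts)
    return summary.sort_values("n_species_top", ascending=False)


def plot_importance_summary(summary: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(summary) + 1.5))
    ax.barh(summary.index[::-1], summary["n_species_top"][::-1])
    ax.set_xlabel("species for which covariate is most important")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
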