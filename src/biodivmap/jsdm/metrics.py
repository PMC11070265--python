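"""Rank-based evaluation metrics."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc", "auc_per_species"]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; ties contribute 1/2.

    Returns ``nan`` when labels contain a single class (the AUC is then
    undefined — e.g. a species absent from a test fold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_per_species(prob: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise AUC for a (samples x species) probability matrix."""
    prob = np.asarray(prob, dtype=float)
    Y = np.asarray(Y)
    return np.array([auc(prob[:, j], Y[:, j]) for j in range(Y.shape[1])])
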