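"""Monte Carlo multivariate-probit likelihood with analytic gradients.

The model is a low-rank latent-factor probit: with linear predictor
``eta_ij`` and species loadings ``Lambda`` (S x r), the likelihood of a
sample's binary vector is

    E_{h ~ N(0, I_r)}  prod_j  Bernoulli( y_ij | Phi(eta_ij + Lambda_j . h) )

estimated by averaging over M fixed standard-normal draws of ``h``.
For ``r = 0`` the expectation collapses and the loss equals the
independent-probit negative log-likelihood exactly (no MC error).
Probabilities are clamped to ``[eps, 1 - eps]`` inside the logs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, ndtr

__all__ = ["bernoulli_probit_loglik", "mc_loglik_draws", "mc_probit_nll", "EPS"]

EPS = 1e-7
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def bernoulli_probit_loglik(z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise ``log Bern(y | Phi(z))`` and its derivative wrt z."""
    p = ndtr(z)
    clipped = (p < EPS) | (p > 1.0 - EPS)
    pc = np.clip(p, EPS, 1.0 - EPS)
    ll = y * np.log(pc) + (1.0 - y) * np.log1p(-pc)
    phi = _INV_SQRT_2PI * np.exp(-0.5 * z**2)
    grad = phi * (y / pc - (1.0 - y) / (1.0 - pc))
    grad = np.where(clipped, 0.0, grad)
    return ll, grad


def mc_loglik_draws(
    eta: np.ndarray, Y: np.ndarray, loadings: np.ndarray, draws: np.ndarray
) -> np.ndarray:
    """Per-(sample, draw) joint log-likelihood matrix, shape (n, M)."""
    z = eta[:, None, :] + (draws @ loadings.T)[None, :, :]
    ll, _ = bernoulli_probit_loglik(z, Y[:, None, :])
    return ll.sum(axis=2)


def mc_probit_nll(
    eta: np.ndarray,
    Y: np.ndarray,
    loadings: np.ndarray | None = None,
    n_draws: int = 100,
    seed: int = 0,
    draws: np.ndarray | None = None,
    return_grads: bool = False,
):
    """Negative log Monte Carlo likelihood (summed over samples).

    Parameters
    ----------
    eta
        Linear predictors, shape (n_samples, n_species).
    Y
        Binary responses, same shape.
    loadings
        Species loadings (n_species, latent_rank); ``None`` or zero
        columns means the independent-probit closed form.
    n_draws, seed
        Number of latent draws and the RNG seed used when ``draws`` is
        not supplied.
    draws
        Optional pre-drawn latent matrix (M, latent_rank); supplying the
        same draws across evaluations makes the loss a deterministic,
        smooth function of the parameters (common random numbers).
    return_grads
        Also return ``(d_eta, d_loadings)`` of the loss.
    """
    eta = np.asarray(eta, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if eta.shape != Y.shape:
        raise ValueError("eta and Y shapes differ")
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite values in linear predictor")
    if not np.all((Y == 0) | (Y == 1)):
        raise ValueError("Y must be binary")
    rank = 0 if loadings is None else loadings.shape[1]
    if rank == 0:
        ll, grad = bernoulli_probit_loglik(eta, Y)
        loss = -float(ll.sum())
        if not return_grads:
            return loss
        d_load = None if loadings is None else np.zeros_like(loadings)
        return loss, -grad, d_load
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if draws is None:
        draws = np.random.default_rng(seed).standard_normal((n_draws, rank))
    M = draws.shape[0]
    z = eta[:, None, :] + (draws @ loadings.T)[None, :, :]  # (n, M, S)
    ll, grad = bernoulli_probit_loglik(z, Y[:, None, :])
    l_im = ll.sum(axis=2)  # (n, M)
    lse = logsumexp(l_im, axis=1)
    loss = float(np.sum(np.log(M) - lse))
    if not return_grads:
        return loss
    w = np.exp(l_im - lse[:, None])  # softmax over draws, rows sum to 1
    gz = -w[:, :, None] * grad  # dLoss/dz
    d_eta = gz.sum(axis=1)
    d_loadings = np.einsum("imj,mr->jr", gz, draws)
    return loss, d_eta, d_loadings
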