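"""Probabilistic site irreplaceability.

A species' predicted landscape occupancy is a Poisson-binomial count
over pixels. A pixel's alpha irreplaceability for species j is the
probability that the pixel is occupied AND exactly pivotal for reaching
the species' conservation target t_j (an integer threshold derived from
a fraction of total expected incidence); beta combines alphas across
species as the probability the pixel is pivotal for at least one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geotiff import RasterStack, write_geotiff
from .maps import ProbabilityMaps

logger = logging.getLogger(__name__)

__all__ = [
    "IrreplaceabilityResult",
    "poisson_binomial_pmf",
    "conservation_threshold",
    "alpha_irreplaceability",
    "beta_irreplaceability",
    "irreplaceability_map",
]


def poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_i), by DP convolution.

    O(n^2); returns a vector over counts 0..n summing to 1 up to float
    accumulation error.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # counts above i+1 are still zero; update in place, high to low
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def conservation_threshold(p: np.ndarray, fraction: float = 0.5) -> int:
    """Integer target t = ceil(fraction * total expected incidence)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return int(np.ceil(fraction * float(np.sum(p)) - 1e-12))


def _pmf_without_each(p: np.ndarray, pmf: np.ndarray, k: int) -> np.ndarray:
    """P(X_{-i} = k) for every i, by deconvolving pixel i from the full PMF.

    Uses the upward recursion for p_i <= 1/2 and the downward recursion
    for p_i > 1/2; both are numerically stable in their half and each
    costs O(n) per k-range, O(n) per pixel overall.
    """
    n = p.size
    out = np.empty(n)
    lo = p <= 0.5
    if np.any(lo):
        # q_0 = f_0 / (1-p); q_m = (f_m - p q_{m-1}) / (1-p)
        pi = p[lo]
        q = pmf[0] / (1.0 - pi)
        for m in range(1, k + 1):
            q = (pmf[m] - pi * q) / (1.0 - pi)
        out[lo] = q
    hi = ~lo
    if np.any(hi):
        # q_{n-1} = f_n / p; q_{m-1} = (f_m - (1-p) q_m) / p
        pi = p[hi]
        q = pmf[n] / pi
        for m in range(n - 1, k, -1):
            q = (pmf[m] - (1.0 - pi) * q) / pi
        out[hi] = q
    return np.clip(out, 0.0, 1.0)


def alpha_irreplaceability(
    p: np.ndarray,
    fraction: float = 0.5,
    pixel: int | None = None,
    threshold: int | None = None,
) -> np.ndarray | float:
    """Per-pixel alpha for one species: alpha_i = p_i * P(X_{-i} = t - 1).

    ``X_{-i}`` is the Poisson-binomial count over all other pixels and
    ``t`` the integer conservation threshold (derived from ``fraction``
    unless ``threshold`` is given explicitly); alpha_i is the
    probability that pixel i is occupied and its loss alone drops the
    count below target. Returns the full vector, or a scalar when
    ``pixel`` given.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    t = conservation_threshold(p, fraction) if threshold is None else int(threshold)
    n = p.size
    if t < 1:
        alpha = np.zeros(n)
    elif t > n:
        logger.warning("conservation target %d unreachable with %d pixels", t, n)
        alpha = np.zeros(n)
    else:
        pmf = poisson_binomial_pmf(p)
        alpha = p * _pmf_without_each(p, pmf, t - 1)
        alpha = np.clip(alpha, 0.0, 1.0)
    if pixel is not None:
        if not 0 <= pixel < n:
            raise IndexError(f"pixel {pixel} out of range for {n} pixels")
        return float(alpha[pixel])
    return alpha


def beta_irreplaceability(alpha: np.ndarray) -> np.ndarray:
    """beta_i = 1 - prod_j (1 - alpha_ij): pivotal for at least one species."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha values must lie in [0, 1]")
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    return 1.0 - np.prod(1.0 - alpha, axis=1)


@dataclass
class IrreplaceabilityResult:
    alpha: np.ndarray  # (n_units, n_species)
    beta: np.ndarray  # (n_units,)
    species_ids: list[str]
    thresholds: np.ndarray  # integer target per species
    fraction: float
    beta_raster: np.ndarray  # (rows, cols), expanded back to pixels
    mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0
    block_size: int = 1

    def write_geotiff(self, path) -> None:
        write_geotiff(
            path,
            RasterStack(
                self.beta_raster[None],
                ["irreplaceability"],
                origin=self.origin,
                pixel_size=self.pixel_size,
                mask=self.mask,
            ),
        )


def _block_aggregate(probs: np.ndarray, mask: np.ndarray, block: int):
    """Mean probability per block x block planning unit (masked pixels excluded)."""
    S, rows, cols = probs.shape
    br = int(np.ceil(rows / block))
    bc = int(np.ceil(cols / block))
    unit_p = np.zeros((S, br, bc))
    unit_mask = np.ones((br, bc), dtype=bool)
    for r in range(br):
        for c in range(bc):
            sl = (slice(r * block, (r + 1) * block), slice(c * block, (c + 1) * block))
            valid = ~mask[sl]
            if valid.any():
                unit_mask[r, c] = False
                unit_p[:, r, c] = probs[(slice(None), *sl)][:, valid].mean(axis=1)
    return unit_p, unit_mask


def irreplaceability_map(
    maps: ProbabilityMaps,
    fraction: float = 0.5,
    block_size: int = 1,
    max_units: int = 20000,
) -> IrreplaceabilityResult:
    """Alpha (per species) and beta irreplaceability for every pixel/unit.

    The exact computation is O(n_species * n_units^2); for large rasters
    pass ``block_size`` > 1 to pool pixels into planning units (mean
    probability per block) first. Exceeding ``max_units`` raises.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if block_size > 1:
        unit_p, unit_mask = _block_aggregate(maps.probs, maps.mask, block_size)
    else:
        unit_p, unit_mask = maps.probs, maps.mask
    valid = ~unit_mask
    n_units = int(valid.sum())
    if n_units > max_units:
        raise ValueError(
            f"{n_units} planning units exceed the compute budget ({max_units}); "
            "increase block_size to aggregate pixels into larger units"
        )
    P = unit_p[:, valid].T  # (n_units, S)
    S = P.shape[1]
    alpha = np.zeros((n_units, S))
    thresholds = np.zeros(S, dtype=int)
    for j in range(S):
        thresholds[j] = conservation_threshold(P[:, j], fraction)
        alpha[:, j] = alpha_irreplaceability(P[:, j], fraction)
    beta = beta_irreplaceability(alpha)
    # expand unit betas back onto the pixel grid for mapping
    beta_units = np.zeros(unit_mask.shape)
    beta_units[valid] = beta
    if block_size > 1:
        beta_raster = np.repeat(np.repeat(beta_units, block_size, 0), block_size, 1)
        rows, cols = maps.grid_shape
        beta_raster = beta_raster[:rows, :cols]
        beta_raster[maps.mask] = 0.0
    else:
        beta_raster = beta_units
    return IrreplaceabilityResult(
        alpha=alpha,
        beta=beta,
        species_ids=list(maps.species_ids),
        thresholds=thresholds,
        fraction=fraction,
        beta_raster=beta_raster,
        mask=maps.mask,
        origin=maps.origin,
        pixel_size=maps.pixel_size,
        block_size=block_size,
    )
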