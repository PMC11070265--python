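"""Synthetic landscapes, species response surfaces and sampled incidence.

Everything here is a pure function of its arguments and a seed, so the
whole downstream pipeline can be exercised and checked against known
generative truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr
from scipy.stats import norm

from .geotiff import RasterStack
from .tables import CovariateTable, IncidenceMatrix

__all__ = [
    "SyntheticLandscape",
    "SpeciesResponseSpec",
    "SamplingDesign",
    "generate_landscape",
    "generate_species",
    "make_design",
    "true_probability",
    "simulate_incidence",
    "extract_site_covariates",
]

RESPONSE_SHAPES = ("linear", "quadratic", "threshold")


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class SyntheticLandscape:
    """Named stack of standardized, spatially autocorrelated covariate layers.

    ``layers`` has shape ``(n_covariates, rows, cols)``; every layer has
    mean 0 and sd 1 over non-masked pixels.
    """

    layers: np.ndarray
    covariate_names: list[str]
    pixel_size: float = 30.0
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must have shape (n_covariates, rows, cols)")
        if self.mask is None:
            self.mask = np.zeros(self.grid_shape, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.layers.shape[1], self.layers.shape[2]

    @property
    def n_covariates(self) -> int:
        return self.layers.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.layers.shape[1] * self.layers.shape[2]

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.grid_shape
        x = (np.arange(cols) + 0.5) * self.pixel_size
        y = (rows - np.arange(rows) - 0.5) * self.pixel_size
        return (
            np.broadcast_to(x, (rows, cols)).copy(),
            np.broadcast_to(y[:, None], (rows, cols)).copy(),
        )

    def pixel_matrix(self) -> np.ndarray:
        """Flattened (n_pixels, n_covariates) covariate matrix, row-major."""
        return self.layers.reshape(self.n_covariates, -1).T

    def pixel_coords(self) -> np.ndarray:
        """Flattened (n_pixels, 2) pixel-centre coordinates, row-major."""
        gx, gy = self.pixel_centres()
        return np.column_stack([gx.ravel(), gy.ravel()])

    def to_raster_stack(self) -> RasterStack:
        rows, _ = self.grid_shape
        return RasterStack(
            data=self.layers,
            band_names=list(self.covariate_names),
            origin=(0.0, rows * self.pixel_size),
            pixel_size=self.pixel_size,
            mask=self.mask,
        )


def generate_landscape(
    grid_shape: tuple[int, int],
    n_covariates: int,
    autocorr_range: float,
    seed: int,
    pixel_size: float = 30.0,
) -> SyntheticLandscape:
    """Gaussian random fields by kernel-smoothing white noise.

    ``autocorr_range`` is the Gaussian smoothing sigma in pixels; 0
    yields plain white noise.  Layers are exactly standardized after
    smoothing.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid dimensions must be positive, got {grid_shape}")
    if n_covariates < 1:
        raise ValueError("n_covariates must be >= 1")
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    rng = np.random.default_rng(seed)
    layers = rng.standard_normal((n_covariates, rows, cols))
    if autocorr_range > 0:
        for i in range(n_covariates):
            layers[i] = gaussian_filter(layers[i], sigma=autocorr_range, mode="reflect")
    # exact standardization over the (unmasked) grid
    flat = layers.reshape(n_covariates, -1)
    layers = ((flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)).reshape(
        layers.shape
    )
    names = [f"cov_{i + 1:02d}" for i in range(n_covariates)]
    return SyntheticLandscape(layers=layers, covariate_names=names, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Species responses
# ---------------------------------------------------------------------------


@dataclass
class ResponseTerm:
    covariate: int
    shape: str  # linear | quadratic | threshold
    coef: float
    coef2: float = 0.0  # quadratic term
    cutpoint: float = 0.0  # threshold location

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            return self.coef * x
        if self.shape == "quadratic":
            return self.coef * x + self.coef2 * x**2
        if self.shape == "threshold":
            return self.coef * (x > self.cutpoint).astype(float)
        raise ValueError(f"unknown response shape {self.shape!r}")


@dataclass
class SpeciesResponseSpec:
    """Generative truth: per-species response terms, intercepts, loadings."""

    covariate_names: list[str]
    terms: list[list[ResponseTerm]]  # one list per species
    intercepts: np.ndarray
    loadings: np.ndarray  # (n_species, latent_rank)
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != self.n_species:
            raise ValueError("loadings must be (n_species, latent_rank)")
        if any(len(t) == 0 for t in self.terms):
            raise ValueError("every species needs at least one active covariate")
        if not self.species_ids:
            self.species_ids = [f"sp_{j + 1:03d}" for j in range(self.n_species)]

    @property
    def n_species(self) -> int:
        return len(self.terms)

    @property
    def latent_rank(self) -> int:
        return self.loadings.shape[1]

    def active_covariates(self, j: int) -> list[int]:
        return [t.covariate for t in self.terms[j]]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Latent-scale predictor eta (incl. intercept) for rows of X."""
        n = X.shape[0]
        eta = np.tile(self.intercepts, (n, 1))
        for j, terms in enumerate(self.terms):
            for t in terms:
                eta[:, j] += t.evaluate(X[:, t.covariate])
        return eta

    def to_dict(self) -> dict:
        return {
            "covariate_names": self.covariate_names,
            "species_ids": self.species_ids,
            "intercepts": self.intercepts.tolist(),
            "loadings": self.loadings.tolist(),
            "terms": [
                [
                    {
                        "covariate": t.covariate,
                        "shape": t.shape,
                        "coef": t.coef,
                        "coef2": t.coef2,
                        "cutpoint": t.cutpoint,
                    }
                    for t in terms
                ]
                for terms in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesResponseSpec":
        return cls(
            covariate_names=list(d["covariate_names"]),
            terms=[[ResponseTerm(**t) for t in terms] for terms in d["terms"]],
            intercepts=np.asarray(d["intercepts"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            species_ids=list(d["species_ids"]),
        )


def _marginal_prob(eta: np.ndarray, loadings_row: np.ndarray) -> np.ndarray:
    # Phi(eta / sqrt(1 + ||Lambda_j||^2)): latent Lambda h + eps folded into
    # the probit scale so the marginal is exact.
    scale = np.sqrt(1.0 + float(np.sum(loadings_row**2)))
    return ndtr(eta / scale)


def _calibrate_intercept(
    eta0: np.ndarray, loadings_row: np.ndarray, target: float, tol: float = 1e-10
) -> float:
    """Bisection on the intercept so landscape-mean occurrence = target."""
    lo, hi = -12.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(_marginal_prob(eta0 + mid, loadings_row)))
        if abs(p - target) < tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_species(
    landscape: SyntheticLandscape,
    n_species: int,
    latent_rank: int,
    sparsity: float,
    seed: int,
    shapes: tuple[str, ...] = RESPONSE_SHAPES,
    prevalence_range: tuple[float, float] = (0.15, 0.85),
    coef_scale: float = 1.5,
    loading_scale: float = 0.6,
) -> SpeciesResponseSpec:
    """Draw sparse nonlinear species responses with calibrated prevalence.

    Each species activates ``max(1, round(sparsity * n_covariates))``
    covariates; its intercept is calibrated by bisection so its marginal
    landscape prevalence hits a target drawn from ``prevalence_range``.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must be in (0, 1]")
    if latent_rank < 0:
        raise ValueError("latent_rank must be >= 0")
    if latent_rank > n_species:
        raise ValueError(f"latent_rank ({latent_rank}) exceeds n_species ({n_species})")
    unknown = set(shapes) - set(RESPONSE_SHAPES)
    if unknown:
        raise ValueError(f"unknown response shapes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    p = landscape.n_covariates
    n_active = max(1, int(round(sparsity * p)))
    X = landscape.pixel_matrix()
    terms: list[list[ResponseTerm]] = []
    loadings = loading_scale * rng.standard_normal((n_species, latent_rank))
    intercepts = np.zeros(n_species)
    targets = rng.uniform(*prevalence_range, size=n_species)
    for j in range(n_species):
        active = rng.choice(p, size=n_active, replace=False)
        sp_terms = []
        for k in active:
            shape = shapes[rng.integers(len(shapes))]
            sign = -1.0 if rng.random() < 0.5 else 1.0
            coef = sign * coef_scale * rng.uniform(0.7, 1.3)
            sp_terms.append(
                ResponseTerm(
                    covariate=int(k),
                    shape=shape,
                    coef=float(coef),
                    coef2=float(0.5 * coef_scale * rng.uniform(-1.0, 1.0)),
                    cutpoint=float(rng.uniform(-0.5, 0.5)),
                )
            )
        terms.append(sp_terms)
    spec = SpeciesResponseSpec(
        covariate_names=list(landscape.covariate_names),
        terms=terms,
        intercepts=intercepts,
        loadings=loadings,
    )
    eta0 = spec.linear_predictor(X)  # intercepts all zero here
    for j in range(n_species):
        spec.intercepts[j] = _calibrate_intercept(eta0[:, j], loadings[j], float(targets[j]))
    return spec


# ---------------------------------------------------------------------------
# Truth surfaces
# ---------------------------------------------------------------------------


def true_probability(spec: SpeciesResponseSpec, landscape: SyntheticLandscape) -> np.ndarray:
    """Exact marginal occurrence probability, shape (n_species, rows, cols)."""
    if list(spec.covariate_names) != list(landscape.covariate_names):
        raise ValueError("species spec and landscape disagree on covariate schema")
    X = landscape.pixel_matrix()
    eta = spec.linear_predictor(X)
    probs = np.empty_like(eta)
    for j in range(spec.n_species):
        probs[:, j] = _marginal_prob(eta[:, j], spec.loadings[j])
    rows, cols = landscape.grid_shape
    return probs.T.reshape(spec.n_species, rows, cols)


# ---------------------------------------------------------------------------
# Sampling design and incidence simulation
# ---------------------------------------------------------------------------


@dataclass
class SamplingDesign:
    """Point locations plus a sample -> point map (paired traps allowed)."""

    point_pixels: np.ndarray  # flat row-major pixel index per point
    sample_point: np.ndarray  # point index per sample
    point_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.point_pixels = np.asarray(self.point_pixels, dtype=int)
        self.sample_point = np.asarray(self.sample_point, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids")
        if self.sample_point.min(initial=0) < 0 or (
            self.sample_point.size and self.sample_point.max() >= len(self.point_pixels)
        ):
            raise ValueError("sample_point refers to an unknown point")

    @property
    def n_points(self) -> int:
        return len(self.point_pixels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_point)

    def sample_pixels(self) -> np.ndarray:
        return self.point_pixels[self.sample_point]


def make_design(
    landscape: SyntheticLandscape,
    n_points: int,
    paired_fraction: float,
    seed: int,
) -> SamplingDesign:
    """Place points on distinct pixels; a fraction get a second trap."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must be in [0, 1]")
    if n_points > landscape.n_pixels:
        raise ValueError("more points than pixels")
    rng = np.random.default_rng(seed)
    valid = np.flatnonzero(~landscape.mask.ravel())
    point_pixels = rng.choice(valid, size=n_points, replace=False)
    n_paired = int(round(paired_fraction * n_points))
    paired = rng.choice(n_points, size=n_paired, replace=False)
    is_paired = np.zeros(n_points, dtype=bool)
    is_paired[paired] = True
    sample_point, sample_ids = [], []
    counter = 0
    for pt in range(n_points):
        for trap in range(2 if is_paired[pt] else 1):
            counter += 1
            sample_point.append(pt)
            sample_ids.append(f"s{counter:04d}")
    point_ids = [f"p{pt + 1:03d}" for pt in range(n_points)]
    return SamplingDesign(
        point_pixels=point_pixels,
        sample_point=np.asarray(sample_point),
        point_ids=point_ids,
        sample_ids=sample_ids,
    )


def simulate_incidence(
    spec: SpeciesResponseSpec,
    landscape: SyntheticLandscape,
    design: SamplingDesign,
    seed: int,
) -> IncidenceMatrix:
    """Draw presence/absence at the design's samples.

    Each sample gets its own latent factor draw (paired traps are
    independent given the pixel), so residual inter-species correlation
    follows the loading matrix while marginals match
    :func:`true_probability`.
    """
    if list(spec.covariate_names) != list(landscape.covariate_names):
        raise ValueError("species spec and landscape disagree on covariate schema")
    pixels = design.sample_pixels()
    if pixels.max(initial=0) >= landscape.n_pixels:
        raise ValueError("design points fall outside the grid")
    X = landscape.pixel_matrix()[pixels]
    eta = spec.linear_predictor(X)  # (n_samples, S)
    rng = np.random.default_rng(seed)
    n, S = eta.shape
    r = spec.latent_rank
    h = rng.standard_normal((n, r)) if r > 0 else np.zeros((n, 0))
    eps = rng.standard_normal((n, S))
    z = eta + h @ spec.loadings.T + eps
    values = (z > 0).astype(np.int8)
    coords = landscape.pixel_coords()[pixels]
    return IncidenceMatrix(
        values=values,
        sample_ids=list(design.sample_ids),
        point_ids=[design.point_ids[pt] for pt in design.sample_point],
        species_ids=list(spec.species_ids),
        x=coords[:, 0],
        y=coords[:, 1],
    )


def extract_site_covariates(
    landscape: SyntheticLandscape, design: SamplingDesign
) -> CovariateTable:
    """Covariate values at each sample's pixel (raw landscape units)."""
    X = landscape.pixel_matrix()[design.sample_pixels()]
    return CovariateTable(
        values=X,
        covariate_names=list(landscape.covariate_names),
        sample_ids=list(design.sample_ids),
    )
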