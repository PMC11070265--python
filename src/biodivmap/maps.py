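"""Landscape prediction and biodiversity summaries.

Per-species occurrence-probability rasters (chunked, bit-identical to
whole-array prediction), AUC-based species filtering, thresholded
species richness and a t-SNE community-composition embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .geotiff import RasterStack, write_geotiff
from .jsdm import JSDMModel

logger = logging.getLogger(__name__)

__all__ = [
    "ProbabilityMaps",
    "RichnessMap",
    "CompositionMap",
    "filter_species_by_auc",
    "predict_raster",
    "richness_map",
    "composition_map",
]


@dataclass
class ProbabilityMaps:
    """Per-species occurrence-probability rasters on one shared grid."""

    probs: np.ndarray  # (n_species, rows, cols)
    species_ids: list[str]
    mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        valid = self.probs[:, ~self.mask]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("probabilities outside [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.probs.shape[1], self.probs.shape[2]

    @property
    def n_species(self) -> int:
        return self.probs.shape[0]

    def subset(self, species_ids: list[str]) -> "ProbabilityMaps":
        idx = [self.species_ids.index(s) for s in species_ids]
        return ProbabilityMaps(
            probs=self.probs[idx],
            species_ids=list(species_ids),
            mask=self.mask,
            origin=self.origin,
            pixel_size=self.pixel_size,
        )

    def pixel_matrix(self) -> np.ndarray:
        """(n_valid_pixels, n_species) matrix over unmasked pixels."""
        return self.probs[:, ~self.mask].T

    def write_geotiffs(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for j, sp in enumerate(self.species_ids):
            path = outdir / f"{sp}.tif"
            write_geotiff(
                path,
                RasterStack(
                    self.probs[j : j + 1],
                    [sp],
                    origin=self.origin,
                    pixel_size=self.pixel_size,
                    mask=self.mask,
                ),
            )
            paths.append(path)
        return paths


@dataclass
class RichnessMap:
    counts: np.ndarray  # (rows, cols) int
    threshold: float
    mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0

    def write_geotiff(self, path) -> None:
        write_geotiff(
            path,
            RasterStack(
                self.counts[None].astype(float),
                ["richness"],
                origin=self.origin,
                pixel_size=self.pixel_size,
                mask=self.mask,
            ),
            dtype="int16",
        )


@dataclass
class CompositionMap:
    axes: np.ndarray  # (2, rows, cols)
    mask: np.ndarray
    subsample_idx: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0

    def write_geotiffs(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i in range(2):
            path = outdir / f"tsne_{i + 1}.tif"
            write_geotiff(
                path,
                RasterStack(
                    self.axes[i : i + 1],
                    [f"tsne_{i + 1}"],
                    origin=self.origin,
                    pixel_size=self.pixel_size,
                    mask=self.mask,
                ),
            )
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------


def filter_species_by_auc(auc_by_species: dict, min_auc: float = 0.7) -> list[str]:
    """Retain species with predictive AUC >= min_auc (inclusive); nan excluded."""
    retained = [
        sp
        for sp, a in auc_by_species.items()
        if a is not None and np.isfinite(a) and a >= min_auc
    ]
    if not retained:
        logger.warning("no species pass the AUC >= %.2f filter", min_auc)
    return retained


def predict_raster(
    model: JSDMModel, stack: RasterStack, chunk_size: int = 65536
) -> ProbabilityMaps:
    """Predict per-pixel marginal occurrence probability for every species.

    Band names must match the model's training covariate schema exactly
    (order included). Prediction runs over flattened unmasked pixels in
    chunks; per-pixel arithmetic is batch-size independent, so chunked
    and whole-array runs are bit-identical. NoData pixels propagate.
    """
    if hasattr(stack, "to_raster_stack"):  # accept a SyntheticLandscape
        stack = stack.to_raster_stack()
    if list(stack.band_names) != list(model.covariate_names):
        raise ValueError(
            f"raster bands {stack.band_names} do not match model covariates "
            f"{model.covariate_names}"
        )
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    rows, cols = stack.grid_shape
    X = stack.data.reshape(stack.n_bands, -1).T
    gx, gy = stack.pixel_centres()
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    valid = np.flatnonzero(~stack.mask.ravel())
    probs = np.full((rows * cols, model.n_species), np.nan)
    for start in range(0, valid.size, chunk_size):
        idx = valid[start : start + chunk_size]
        probs[idx] = model.predict_prob(X[idx], coords[idx], rowwise=True)
    probs = probs.T.reshape(model.n_species, rows, cols)
    probs[:, stack.mask] = 0.0  # masked pixels carry no probability
    return ProbabilityMaps(
        probs=probs,
        species_ids=list(model.species_ids),
        mask=stack.mask.copy(),
        origin=stack.origin,
        pixel_size=stack.pixel_size,
    )


def richness_map(maps: ProbabilityMaps, threshold: float = 0.5) -> RichnessMap:
    """Per pixel, number of species with probability >= threshold (inclusive)."""
    counts = (maps.probs >= threshold).sum(axis=0).astype(np.int16)
    counts[maps.mask] = 0
    return RichnessMap(
        counts=counts,
        threshold=threshold,
        mask=maps.mask,
        origin=maps.origin,
        pixel_size=maps.pixel_size,
    )


def composition_map(
    maps: ProbabilityMaps,
    method: str = "tsne",
    perplexity: float = 30.0,
    max_pixels: int = 10000,
    seed: int = 0,
) -> CompositionMap:
    """2-D embedding of pixels in species-probability space.

    If the landscape exceeds ``max_pixels``, a seeded random subsample
    is embedded and remaining pixels take the embedding of their
    nearest neighbour in species space (so identical compositions get
    identical coordinates). Axes are sign/rotation arbitrary.
    """
    if method != "tsne":
        raise ValueError(f"unknown method {method!r}")
    features = maps.pixel_matrix()
    n = features.shape[0]
    if n < 3:
        raise ValueError("need at least 3 unmasked pixels")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of pixels ({n})")
    rng = np.random.default_rng(seed)
    if n > max_pixels:
        sub = np.sort(rng.choice(n, size=max_pixels, replace=False))
    else:
        sub = np.arange(n)
    tsne = TSNE(
        n_components=2,
        perplexity=min(perplexity, max(1.0, (len(sub) - 1) / 3.0)),
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    emb_sub = np.asarray(tsne.fit_transform(features[sub]), dtype=float)
    if len(sub) < n:
        nn = NearestNeighbors(n_neighbors=1).fit(features[sub])
        _, nearest = nn.kneighbors(features)
        emb = emb_sub[nearest[:, 0]]
        emb[sub] = emb_sub
    else:
        emb = emb_sub
    rows, cols = maps.grid_shape
    axes = np.zeros((2, rows, cols))
    flat_valid = ~maps.mask.ravel()
    for i in range(2):
        layer = np.zeros(rows * cols)
        layer[flat_valid] = emb[:, i]
        axes[i] = layer.reshape(rows, cols)
    return CompositionMap(
        axes=axes,
        mask=maps.mask,
        subsample_idx=sub,
        origin=maps.origin,
        pixel_size=maps.pixel_size,
    )
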