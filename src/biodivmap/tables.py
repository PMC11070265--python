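"""Community and covariate table preprocessing.

Presence calling from barcode-coverage summaries, rare-species
filtering, iterative VIF-based covariate reduction, and the train/test
split used by the modelling stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IncidenceMatrix",
    "CovariateTable",
    "TrainTestSplit",
    "read_coverage_table",
    "call_presences",
    "filter_by_incidence",
    "compute_vifs",
    "reduce_covariates_vif",
    "split_train_test",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class IncidenceMatrix:
    """Samples x species binary matrix with sample/point identity."""

    values: np.ndarray
    sample_ids: list[str]
    point_ids: list[str]
    species_ids: list[str]
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("incidence values must be 2-D (samples x species)")
        uniq = set(self.values.ravel().tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"incidence entries must be 0/1, found {sorted(uniq - {0, 1})[:5]}")
        self.values = self.values.astype(np.int8)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match rows")
        if len(self.point_ids) != self.values.shape[0]:
            raise ValueError("point_ids length does not match rows")
        if len(self.species_ids) != self.values.shape[1]:
            raise ValueError("species_ids length does not match columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for attr in ("x", "y"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def incidence(self) -> np.ndarray:
        """Per-species number of samples in which it occurs."""
        return self.values.sum(axis=0)

    def subset_samples(self, idx: np.ndarray) -> "IncidenceMatrix":
        idx = np.asarray(idx)
        return IncidenceMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            point_ids=[self.point_ids[i] for i in idx],
            species_ids=list(self.species_ids),
            x=None if self.x is None else self.x[idx],
            y=None if self.y is None else self.y[idx],
        )

    def subset_species(self, idx: np.ndarray) -> "IncidenceMatrix":
        idx = np.asarray(idx)
        return IncidenceMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            point_ids=list(self.point_ids),
            species_ids=[self.species_ids[i] for i in idx],
            x=self.x,
            y=self.y,
        )

    @property
    def coords(self) -> np.ndarray:
        if self.x is None or self.y is None:
            raise ValueError("incidence matrix has no coordinates")
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "point_id", self.point_ids)
        df.insert(2, "x", self.x if self.x is not None else np.nan)
        df.insert(3, "y", self.y if self.y is not None else np.nan)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IncidenceMatrix":
        df = pd.read_csv(path)
        meta = ["sample_id", "point_id", "x", "y"]
        species = [c for c in df.columns if c not in meta]
        x = df["x"].to_numpy() if "x" in df else None
        y = df["y"].to_numpy() if "y" in df else None
        return cls(
            values=df[species].to_numpy(),
            sample_ids=df["sample_id"].astype(str).tolist(),
            point_ids=df["point_id"].astype(str).tolist(),
            species_ids=species,
            x=x,
            y=y,
        )


@dataclass
class CovariateTable:
    """Samples x covariates real matrix with optional standardization state.

    ``means``/``sds`` are the training-row standardization parameters;
    they are fitted once on training rows and re-applied verbatim to
    test rows and raster pixels.
    """

    values: np.ndarray
    covariate_names: list[str]
    sample_ids: list[str]
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be 2-D")
        if len(self.covariate_names) != self.values.shape[1]:
            raise ValueError("covariate_names length does not match columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def fit_standardization(self) -> "CovariateTable":
        """Return a copy standardized with parameters fitted on own rows."""
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0)
        sds = np.where(sds == 0, 1.0, sds)
        return CovariateTable(
            values=(self.values - means) / sds,
            covariate_names=list(self.covariate_names),
            sample_ids=list(self.sample_ids),
            means=means,
            sds=sds,
        )

    def apply_standardization(self, means: np.ndarray, sds: np.ndarray) -> "CovariateTable":
        return CovariateTable(
            values=(self.values - means) / sds,
            covariate_names=list(self.covariate_names),
            sample_ids=list(self.sample_ids),
            means=np.asarray(means, dtype=float),
            sds=np.asarray(sds, dtype=float),
        )

    def subset_samples(self, idx: np.ndarray) -> "CovariateTable":
        idx = np.asarray(idx)
        return CovariateTable(
            values=self.values[idx],
            covariate_names=list(self.covariate_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            means=self.means,
            sds=self.sds,
        )

    def subset_covariates(self, names: list[str]) -> "CovariateTable":
        idx = [self.covariate_names.index(n) for n in names]
        return CovariateTable(
            values=self.values[:, idx],
            covariate_names=list(names),
            sample_ids=list(self.sample_ids),
            means=None if self.means is None else self.means[idx],
            sds=None if self.sds is None else self.sds[idx],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.covariate_names)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CovariateTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "sample_id"]
        return cls(
            values=df[names].to_numpy(dtype=float),
            covariate_names=names,
            sample_ids=df["sample_id"].astype(str).tolist(),
        )


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------


def read_coverage_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "species_id", "covered_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return df


def call_presences(
    coverage: pd.DataFrame,
    min_fraction: float = 0.5,
    sample_ids: list[str] | None = None,
    species_ids: list[str] | None = None,
    point_ids: dict[str, str] | None = None,
) -> IncidenceMatrix:
    """Call presence/absence from per-(sample, species) barcode coverage.

    A species is called present in a sample iff its covered fraction is
    *strictly greater* than ``min_fraction``; the 50% boundary itself is
    an absence.  Pairs missing from the table are absences.

    Parameters
    ----------
    coverage
        Long-format table with columns ``sample_id``, ``species_id``,
        ``covered_fraction`` (each pair at most once).
    min_fraction
        Fraction of barcode length that must be exceeded.
    sample_ids, species_ids
        Optional full universes (rows/columns of the output); defaults
        to the ids observed in the table, sorted.
    point_ids
        Optional sample -> point mapping; defaults to the sample id.
    """
    frac = coverage["covered_fraction"].to_numpy(dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("covered_fraction outside [0, 1]")
    if coverage.duplicated(["sample_id", "species_id"]).any():
        raise ValueError("duplicate (sample, species) pairs in coverage table")
    if sample_ids is None:
        sample_ids = sorted(coverage["sample_id"].astype(str).unique())
    if species_ids is None:
        species_ids = sorted(coverage["species_id"].astype(str).unique())
    s_index = {s: i for i, s in enumerate(sample_ids)}
    j_index = {s: j for j, s in enumerate(species_ids)}
    values = np.zeros((len(sample_ids), len(species_ids)), dtype=np.int8)
    hits = coverage[frac > min_fraction]
    for sid, jid in zip(hits["sample_id"].astype(str), hits["species_id"].astype(str)):
        values[s_index[sid], j_index[jid]] = 1
    points = [point_ids.get(s, s) if point_ids else s for s in sample_ids]
    return IncidenceMatrix(values, list(sample_ids), points, list(species_ids))


# ---------------------------------------------------------------------------
# Rare-species filter
# ---------------------------------------------------------------------------


def filter_by_incidence(Y: IncidenceMatrix, min_sites: int = 6) -> IncidenceMatrix:
    """Keep species present in at least ``min_sites`` samples (inclusive)."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if Y.n_samples == 0 or Y.n_species == 0:
        raise ValueError("empty incidence matrix")
    keep = np.flatnonzero(Y.incidence() >= min_sites)
    if keep.size == 0:
        logger.warning("incidence filter removed every species (min_sites=%d)", min_sites)
    return Y.subset_species(keep)


# ---------------------------------------------------------------------------
# VIF reduction
# ---------------------------------------------------------------------------

_VIF_CAP = 1e12


def compute_vifs(values: np.ndarray) -> np.ndarray:
    """Variance inflation factor of every column given all the others.

    VIF_k = 1 / (1 - R^2_k) with R^2_k from an OLS regression (with
    intercept) of column k on the remaining columns.  Perfectly
    collinear columns get a large finite cap instead of infinity.
    """
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 covariates")
    vifs = np.empty(p)
    for k in range(p):
        yk = X[:, k]
        others = np.delete(X, k, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yk, rcond=None)
        resid = yk - design @ beta
        sst = np.sum((yk - yk.mean()) ** 2)
        if sst <= 0:
            vifs[k] = 1.0  # constant column carries no collinearity signal
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs[k] = _VIF_CAP if r2 >= 1.0 - 1.0 / _VIF_CAP else 1.0 / (1.0 - r2)
    return vifs


def reduce_covariates_vif(
    X: CovariateTable, vif_threshold: float = 10.0
) -> tuple[CovariateTable, pd.DataFrame]:
    """Iteratively drop the largest-VIF covariate until all VIFs <= threshold.

    Ties are broken by column order (first maximal column removed).
    Returns the reduced table and a removal log with columns
    ``covariate``, ``vif``, ``step``.
    """
    if X.n_covariates < 2:
        raise ValueError("need at least 2 covariates for VIF reduction")
    if X.n_samples < X.n_covariates:
        raise ValueError(
            f"need at least as many rows ({X.n_samples}) as covariates ({X.n_covariates})"
        )
    names = list(X.covariate_names)
    values = X.values.copy()
    log_rows = []
    step = 0
    while len(names) >= 2:
        vifs = compute_vifs(values)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_threshold:
            break
        step += 1
        log_rows.append({"covariate": names[worst], "vif": float(vifs[worst]), "step": step})
        values = np.delete(values, worst, axis=1)
        del names[worst]
    reduced = X.subset_covariates(names)
    log = pd.DataFrame(log_rows, columns=["covariate", "vif", "step"])
    return reduced, log


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass
class TrainTestSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    Y_train: IncidenceMatrix
    Y_test: IncidenceMatrix
    X_train: CovariateTable
    X_test: CovariateTable


def train_size(n_samples: int, train_fraction: float) -> int:
    """Training-partition size: nearest integer, ties rounded up."""
    return int(np.floor(n_samples * train_fraction + 0.5))


def split_train_test(
    Y: IncidenceMatrix,
    X: CovariateTable,
    train_fraction: float = 0.75,
    seed: int = 0,
    group_by_point: bool = False,
) -> TrainTestSplit:
    """Randomly split samples into train/test partitions.

    With ``group_by_point`` all samples sharing a point move together
    (prevents paired-trap leakage); by default the split is by sample.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = Y.n_samples
    if X.n_samples != n:
        raise ValueError("incidence and covariate tables disagree on sample count")
    rng = np.random.default_rng(seed)
    if group_by_point:
        points = pd.unique(np.asarray(Y.point_ids))
        n_train_pts = train_size(len(points), train_fraction)
        perm = rng.permutation(len(points))
        train_points = set(points[perm[:n_train_pts]])
        train_idx = np.array([i for i, p in enumerate(Y.point_ids) if p in train_points])
        test_idx = np.array([i for i, p in enumerate(Y.point_ids) if p not in train_points])
    else:
        n_train = train_size(n, train_fraction)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError(
            f"empty partition: train={train_idx.size}, test={test_idx.size} "
            f"(n={n}, fraction={train_fraction})"
        )
    return TrainTestSplit(
        train_idx=train_idx,
        test_idx=test_idx,
        Y_train=Y.subset_samples(train_idx),
        Y_test=Y.subset_samples(test_idx),
        X_train=X.subset_samples(train_idx),
        X_test=X.subset_samples(test_idx),
    )
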