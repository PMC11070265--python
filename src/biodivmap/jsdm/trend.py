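"""Polynomial trend surface absorbing broad spatial autocorrelation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrendSurface", "build_trend_surface"]


@dataclass
class TrendSurface:
    """Monomial basis in standardized site coordinates, constant excluded.

    Coordinates are standardized with the training-site mean/sd stored
    here, so transformed values are shift- and scale-invariant.
    """

    degree: int
    coord_mean: np.ndarray
    coord_sd: np.ndarray
    basis_names: list[str]

    @property
    def n_basis(self) -> int:
        return len(self.basis_names)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n_sites, 2)")
        z = (coords - self.coord_mean) / self.coord_sd
        cols = []
        for a, b in _powers(self.degree):
            cols.append(z[:, 0] ** a * z[:, 1] ** b)
        return np.column_stack(cols)


def _powers(degree: int) -> list[tuple[int, int]]:
    out = []
    for total in range(1, degree + 1):
        for a in range(total, -1, -1):
            out.append((a, total - a))
    return out


def _name(a: int, b: int) -> str:
    parts = []
    if a:
        parts.append("x" if a == 1 else f"x^{a}")
    if b:
        parts.append("y" if b == 1 else f"y^{b}")
    return "*".join(parts)


def build_trend_surface(coords: np.ndarray, degree: int = 2) -> TrendSurface:
    """Fit coordinate standardization and lay out the monomial basis."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_sites, 2)")
    if coords.shape[0] < 1:
        raise ValueError("need at least one site")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    mean = coords.mean(axis=0)
    sd = coords.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all sites at one location: trend surface has zero variance")
    sd = np.where(sd == 0, 1.0, sd)
    names = [_name(a, b) for a, b in _powers(degree)]
    return TrendSurface(degree=degree, coord_mean=mean, coord_sd=sd, basis_names=names)
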