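"""Partial-dependence surfaces for one and two features.

Partial dependence at grid value g is the average model prediction over the
empirical sample with the swept feature(s) overwritten by g, exposing the
model's marginal response and, on two-feature grids, interaction structure
(a purely additive model yields a surface equal to the outer sum of its 1-D
curves minus the global mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PDPGrid",
    "quantile_grid",
    "pdp_1d",
    "pdp_2d",
    "nonadditivity",
    "plot_pdp_heatmap",
]


@dataclass(frozen=True)
class PDPGrid:
    feature_a: str
    feature_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    surface: np.ndarray  # shape (len(grid_a), len(grid_b))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (grid_a, grid_b) cell."""
        aa, bb = np.meshgrid(self.grid_a, self.grid_b, indexing="ij")
        return pd.DataFrame({
            self.feature_a: aa.ravel(),
            self.feature_b: bb.ravel(),
            "value": self.surface.ravel(),
        })


def _columns(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return list(map(str, X.columns))
    return [f"x{j}" for j in range(np.asarray(X).shape[1])]


def quantile_grid(X, feature: str, n: int = 20, clip: tuple[float, float] = (0.01, 0.99)) -> np.ndarray:
    """Unique empirical quantiles of a feature, clipped at the 1st/99th
    percentile by default (robust to the skewed provincial indicators)."""
    cols = _columns(X)
    if feature not in cols:
        raise ValueError(f"unknown feature {feature!r}")
    x = np.asarray(X, dtype=float)[:, cols.index(feature)]
    qs = np.linspace(clip[0], clip[1], n)
    return np.unique(np.quantile(x, qs))


def pdp_1d(model, X, feature: str, grid=None, n_grid: int = 20):
    """1-D partial dependence: (grid, mean prediction at each grid value)."""
    cols = _columns(X)
    if feature not in cols:
        raise ValueError(f"unknown feature {feature!r}")
    arr = np.asarray(X, dtype=float)
    grid = quantile_grid(X, feature, n=n_grid) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    j = cols.index(feature)
    n = arr.shape[0]
    # one batched predict: sample tiled per grid value
    Z = np.repeat(arr[None, :, :], grid.size, axis=0)
    Z[:, :, j] = grid[:, None]
    preds = np.asarray(model.predict(Z.reshape(-1, arr.shape[1])), dtype=float)
    return grid, preds.reshape(grid.size, n).mean(axis=1)


def pdp_2d(model, X, feature_a: str, feature_b: str, grid_a=None, grid_b=None,
           n_grid: int = 20) -> PDPGrid:
    """Two-feature partial-dependence surface over the grid product."""
    if feature_a == feature_b:
        raise ValueError("feature_a and feature_b must differ")
    cols = _columns(X)
    for f in (feature_a, feature_b):
        if f not in cols:
            raise ValueError(f"unknown feature {f!r}")
    arr = np.asarray(X, dtype=float)
    ga = quantile_grid(X, feature_a, n=n_grid) if grid_a is None else np.asarray(grid_a, dtype=float)
    gb = quantile_grid(X, feature_b, n=n_grid) if grid_b is None else np.asarray(grid_b, dtype=float)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("empty grid")
    ja, jb = cols.index(feature_a), cols.index(feature_b)
    n = arr.shape[0]
    surface = np.empty((ga.size, gb.size))
    for u, a in enumerate(ga):
        Z = np.repeat(arr[None, :, :], gb.size, axis=0)
        Z[:, :, ja] = a
        Z[:, :, jb] = gb[:, None]
        preds = np.asarray(model.predict(Z.reshape(-1, arr.shape[1])), dtype=float)
        surface[u] = preds.reshape(gb.size, n).mean(axis=1)
    return PDPGrid(feature_a=feature_a, feature_b=feature_b,
                   grid_a=ga, grid_b=gb, surface=surface)


def nonadditivity(model, X, feature_a: str, feature_b: str, grid_a=None, grid_b=None,
                  n_grid: int = 20) -> float:
    """Max |2-D surface - outer-sum reconstruction from the 1-D curves|.

    Zero (to numerical tolerance) for an additive model; grows with genuine
    interaction between the two features.
    """
    pg = pdp_2d(model, X, feature_a, feature_b, grid_a=grid_a, grid_b=grid_b,
                n_grid=n_grid)
    _, pa = pdp_1d(model, X, feature_a, grid=pg.grid_a)
    _, pb = pdp_1d(model, X, feature_b, grid=pg.grid_b)
    base = float(np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=float).mean())
    recon = pa[:, None] + pb[None, :] - base
    return float(np.abs(pg.surface - recon).max())


def plot_pdp_heatmap(grid: PDPGrid, ax=None):
    """Optional heat-map rendering of a 2-D surface (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(grid.grid_b, grid.grid_a, grid.surface, shading="nearest")
    ax.set_xlabel(grid.feature_b)
    ax.set_ylabel(grid.feature_a)
    ax.figure.colorbar(mesh, ax=ax, label="mean prediction")
    return ax
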