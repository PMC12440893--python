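"""Threshold detection on attribution scatters.

A locally linear LOWESS smoother (tricube weights over the span-nearest
neighbours, exact weighted-least-squares solution at every grid point) is fit
to (feature value, attribution) pairs; the threshold is where the smoothed
curve crosses zero, i.e. where the feature's association with the outcome
changes sign.  Uncertainty comes from a seeded bootstrap over the pairs with
percentile confidence intervals, and rise-then-flat patterns are located by a
finite-difference plateau detector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SmoothCurve",
    "ThresholdEstimate",
    "PlateauEstimate",
    "LowessSmoother",
    "lowess_fit",
    "zero_crossings",
    "bootstrap_threshold",
    "detect_plateau",
]

NEG_TO_POS = "neg_to_pos"
POS_TO_NEG = "pos_to_neg"


@dataclass(frozen=True)
class SmoothCurve:
    grid_x: np.ndarray
    fitted_y: np.ndarray
    span: float
    degree: int = 1


@dataclass(frozen=True)
class ThresholdEstimate:
    point: float
    ci_low: float
    ci_high: float
    direction: str
    n_boot: int
    level: float
    unmatched_fraction: float
    unstable: bool
    samples: np.ndarray


@dataclass(frozen=True)
class PlateauEstimate:
    start: float
    slope_tolerance: float


class LowessSmoother(BaseEstimator, RegressorMixin):
    """Locally linear scatterplot smoother with tricube neighbourhood weights.

    At each evaluation point the ceil(span * n) nearest data points (by |x|
    distance) receive tricube weights scaled by the neighbourhood radius, and
    a degree-1 weighted least squares fit supplies the smoothed value.  The
    local fit is solved exactly (closed form), so affine data are reproduced
    to machine precision for every span.

    Parameters
    ----------
    span : float in (0, 1]
        Fraction of the data entering each local fit (default 0.3).
    """

    def __init__(self, span: float = 0.3):
        self.span = span

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        n = x.shape[0]
        k = math.ceil(self.span * n)
        if n < 5 or k < 3:
            raise ValueError(
                f"need n >= 5 and ceil(span*n) >= 3 local points; got n={n}, k={k}"
            )
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        self.y_ = y[order]
        self.k_ = min(k, n)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "x_")
        g = np.asarray(X, dtype=float).ravel()
        # (G, n) distances; panels here are small, so the dense matrix is cheap
        dist = np.abs(g[:, None] - self.x_[None, :])
        radius = np.partition(dist, self.k_ - 1, axis=1)[:, self.k_ - 1]
        safe_r = np.where(radius == 0, 1.0, radius)[:, None]
        w = (1.0 - np.clip(dist / safe_r, 0.0, 1.0) ** 3) ** 3
        zero_radius = radius == 0
        if zero_radius.any():
            # >= k duplicates at the evaluation point: average just those
            w[zero_radius] = (dist[zero_radius] == 0).astype(float)
        # centre x at the evaluation point: the fitted value is the intercept
        xc = self.x_[None, :] - g[:, None]
        s0 = w.sum(axis=1)
        s1 = (w * xc).sum(axis=1)
        s2 = (w * xc**2).sum(axis=1)
        sy = w @ self.y_
        sxy = (w * xc * self.y_[None, :]).sum(axis=1)
        det = s0 * s2 - s1**2
        # guard: all local weight on a single x value -> weighted mean
        scale = np.maximum(s0 * s2, s1**2)
        singular = det <= 1e-12 * np.where(scale > 0, scale, 1.0)
        if singular.any() and not zero_radius.all():
            warnings.warn(
                "singular local design (identical neighbour x); falling back to "
                "weighted mean at affected grid points",
                stacklevel=2,
            )
        slope = np.where(singular, 0.0, (s0 * sxy - s1 * sy) / np.where(singular, 1.0, det))
        return (sy - slope * s1) / s0


def lowess_fit(x, y, span: float = 0.3, grid_x=None, n_grid: int = 200) -> SmoothCurve:
    """Fit the locally linear smoother and evaluate it on a grid.

    ``grid_x`` defaults to ``n_grid`` equally spaced points spanning the
    observed x range.
    """
    x = np.asarray(x, dtype=float).ravel()
    sm = LowessSmoother(span=span).fit(x, y)
    if grid_x is None:
        grid_x = np.linspace(x.min(), x.max(), n_grid)
    else:
        grid_x = np.asarray(grid_x, dtype=float).ravel()
        if np.any(np.diff(grid_x) <= 0):
            raise ValueError("grid_x must be strictly increasing")
    return SmoothCurve(grid_x=grid_x, fitted_y=sm.predict(grid_x), span=span)


def zero_crossings(curve: SmoothCurve) -> list[tuple[float, str]]:
    """Zero crossings of the fitted curve, ordered by x.

    For adjacent grid values with opposite signs the crossing is placed by
    linear interpolation; an exact zero at a grid point is reported once,
    with direction taken from its neighbours.
    """
    gx, fy = curve.grid_x, curve.fitted_y
    out: list[tuple[float, str]] = []
    i = 0
    while i < len(gx) - 1:
        y0, y1 = fy[i], fy[i + 1]
        if y0 == 0.0:
            if i > 0 and fy[i - 1] == 0.0:
                i += 1  # interior of a flat zero run: already reported
                continue
            # direction from the nearest nonzero neighbours
            left = next((fy[j] for j in range(i - 1, -1, -1) if fy[j] != 0), None)
            right = next((fy[j] for j in range(i + 1, len(gx)) if fy[j] != 0), None)
            if left is not None and right is not None and left * right < 0:
                out.append((float(gx[i]), NEG_TO_POS if right > 0 else POS_TO_NEG))
            i += 1
            continue
        if y0 * y1 < 0:
            xc = gx[i] - y0 * (gx[i + 1] - gx[i]) / (y1 - y0)
            out.append((float(xc), NEG_TO_POS if y1 > 0 else POS_TO_NEG))
        i += 1
    return out


def _select_crossing(crossings, near=None, direction=None):
    cands = crossings
    if direction is not None:
        cands = [c for c in cands if c[1] == direction]
    if not cands:
        return None
    if near is not None:
        return min(cands, key=lambda c: abs(c[0] - near))
    if len(cands) > 1:
        raise ValueError(
            f"multiple candidate crossings {[(round(c[0], 4), c[1]) for c in cands]}; "
            "pass `near=` or `direction=` to select one"
        )
    return cands[0]


def bootstrap_threshold(
    x,
    y,
    span: float = 0.3,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    near: float | None = None,
    direction: str | None = None,
    n_grid: int = 200,
) -> ThresholdEstimate:
    """Zero-crossing threshold with a percentile bootstrap confidence interval.

    The full-data crossing is the point estimate (if several crossings exist
    the caller must disambiguate via ``near`` or ``direction``).  The (x, y)
    pairs are resampled with replacement ``n_boot`` times; in each resample
    the smoother is refit on the full-data grid and the crossing matching the
    point estimate (same direction, nearest in x) is recorded.  The CI is the
    percentile interval of recorded crossings; resamples with no matching
    crossing are counted, and the estimate is flagged unstable when they
    exceed half of the resamples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    curve = lowess_fit(x, y, span=span, n_grid=n_grid)
    chosen = _select_crossing(zero_crossings(curve), near=near, direction=direction)
    if chosen is None:
        raise ValueError("no zero crossing on the full data (with the given selection)")
    point, point_dir = chosen
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    samples = []
    unmatched = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bc = lowess_fit(x[idx], y[idx], span=span, grid_x=curve.grid_x)
        match = _select_crossing(zero_crossings(bc), near=point, direction=point_dir)
        if match is None:
            unmatched += 1
        else:
            samples.append(match[0])
    samples = np.asarray(samples)
    frac = unmatched / n_boot
    if samples.size == 0:
        raise ValueError("no bootstrap resample produced a matching crossing")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [100 * alpha, 100 * (1 - alpha)])
    return ThresholdEstimate(
        point=float(point), ci_low=float(lo), ci_high=float(hi),
        direction=point_dir, n_boot=n_boot, level=level,
        unmatched_fraction=frac, unstable=frac > 0.5, samples=samples,
    )


def detect_plateau(curve: SmoothCurve, slope_tolerance: float) -> PlateauEstimate | None:
    """Earliest grid point after which the finite-difference slope stays
    below tolerance through the end of the grid; None if there is no such
    point."""
    gx, fy = curve.grid_x, curve.fitted_y
    if len(gx) < 2:
        raise ValueError("curve must have at least two grid points")
    slopes = np.abs(np.diff(fy) / np.diff(gx))
    flat = slopes < slope_tolerance
    if flat.all():
        return PlateauEstimate(start=float(gx[0]), slope_tolerance=slope_tolerance)
    last_steep = np.nonzero(~flat)[0][-1]
    if last_steep + 1 >= len(flat):
        return None
    return PlateauEstimate(start=float(gx[last_steep + 1]), slope_tolerance=slope_tolerance)
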