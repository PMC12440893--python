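"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with naive loops / generic solvers so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_entropy_topsis(X, signs):
    """Loop transcription of the entropy-TOPSIS recipe.

    X: m x p raw matrix; signs: +1 (higher is better) / -1 per column.
    Returns (closeness, weights).
    """
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    Xn = np.zeros_like(X)
    for j in range(p):
        lo, hi = X[:, j].min(), X[:, j].max()
        for i in range(m):
            if hi == lo:
                Xn[i, j] = 0.0
            elif signs[j] > 0:
                Xn[i, j] = (X[i, j] - lo) / (hi - lo)
            else:
                Xn[i, j] = (hi - X[i, j]) / (hi - lo)
    e = np.zeros(p)
    for j in range(p):
        colsum = Xn[:, j].sum()
        if colsum == 0:
            e[j] = 1.0
            continue
        s = 0.0
        for i in range(m):
            r = Xn[i, j] / colsum
            if r > 0:
                s += r * math.log(r)
        e[j] = -s / math.log(m)
    d = 1.0 - e
    d[np.abs(d) < 1e-15] = 0.0
    w = d / d.sum()
    V = Xn * w
    splus = V.max(axis=0)
    sminus = V.min(axis=0)
    hli = np.zeros(m)
    for i in range(m):
        dp = math.sqrt(sum((V[i, j] - splus[j]) ** 2 for j in range(p)))
        dm = math.sqrt(sum((V[i, j] - sminus[j]) ** 2 for j in range(p)))
        hli[i] = dm / (dp + dm)
    return hli, w


def naive_lowess_point(x, y, g, span):
    """One locally linear tricube fit at point g via lstsq (independent of
    the package's closed-form path)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = math.ceil(span * n)
    dist = np.abs(x - g)
    radius = np.sort(dist)[k - 1]
    if radius == 0:
        sel = dist == 0
        return float(y[sel].mean())
    w = np.clip(1 - np.clip(dist / radius, 0, 1) ** 3, 0, None) ** 3
    sw = np.sqrt(w)
    A = np.column_stack([np.ones(n), x - g]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    return float(beta[0])


def breakpoint_scan(x, y, grid):
    """Least-squares scan for a continuous piecewise-linear breakpoint.

    For each candidate b, fits y ~ 1 + x + max(x - b, 0) by OLS and returns
    the candidate with the smallest SSE.
    """
    best = (np.inf, None)
    for b in grid:
        A = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((y - A @ beta) ** 2).sum())
        if sse < best[0]:
            best = (sse, b)
    return best[1]
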