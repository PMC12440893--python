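"""Per-observation additive feature attributions (Shapley values).

A model prediction is decomposed as ``yhat_i = phi0 + sum_j phi_ij`` (local
accuracy).  Attribution engines:

- ``xgboost_native`` / ``lightgbm_native``: the boosters' built-in TreeSHAP
  contributions (polynomial-time, path-dependent expectations).
- ``linear``: closed-form attributions for linear models,
  ``phi_ij = c_j (x_ij - mean_background_j)`` -- exactly the Shapley values of
  a linear model with independent features.
- ``permutation``: model-agnostic Shapley estimate averaging marginal
  contributions over seeded antithetic feature orderings against an empirical
  background sample.  Whatever the number of orderings, the additivity
  identity holds exactly by telescoping, so local accuracy is preserved.
- ``exact``: brute-force enumeration over all feature subsets (the defining
  weighted sum of marginal contributions); exponential in d, intended as a
  small-d oracle.

Every engine's output is validated against the model's predictions; a
violated identity raises :class:`AdditivityError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "AttributionMatrix",
    "AdditivityError",
    "compute_attributions",
    "exact_shapley",
    "importance_shares",
    "attribution_scatter",
]


class AdditivityError(RuntimeError):
    """The additive attribution identity failed validation."""


@dataclass(frozen=True)
class AttributionMatrix:
    """n x d attribution values, the base value, and the aligned inputs."""

    phi: np.ndarray
    phi0: float
    feature_values: np.ndarray
    feature_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, columns=list(self.feature_names))

    @property
    def predictions(self) -> np.ndarray:
        return self.phi0 + self.phi.sum(axis=1)


def _as_array(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    return arr, tuple(f"x{j}" for j in range(arr.shape[1]))


def _linear_coefficients(model) -> np.ndarray | None:
    """Effective per-feature slope of a linear model or scaler+linear pipeline."""
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    if hasattr(model, "coef_") and hasattr(model, "intercept_"):
        coef = np.asarray(model.coef_, dtype=float).ravel()
        return coef
    if isinstance(model, Pipeline) and len(model.steps) == 2:
        scaler, last = model.steps[0][1], model.steps[1][1]
        if isinstance(scaler, StandardScaler) and hasattr(last, "coef_"):
            coef = np.asarray(last.coef_, dtype=float).ravel()
            scale = scaler.scale_ if scaler.scale_ is not None else 1.0
            return coef / scale
    return None


def _detect_engine(model) -> str:
    name = type(model).__name__
    if hasattr(model, "get_booster") and name.startswith("XGB"):
        return "xgboost_native"
    if hasattr(model, "booster_") and name.startswith("LGBM"):
        return "lightgbm_native"
    if _linear_coefficients(model) is not None:
        return "linear"
    return "permutation"


def _xgboost_contribs(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    import xgboost as xgb

    contribs = model.get_booster().predict(xgb.DMatrix(X), pred_contribs=True)
    return contribs[:, :-1].astype(float), float(contribs[:, -1].mean())


def _lightgbm_contribs(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    contribs = np.asarray(model.predict(X, pred_contrib=True), dtype=float)
    return contribs[:, :-1], float(contribs[:, -1].mean())


def _linear_attributions(model, X: np.ndarray, background: np.ndarray):
    coef = _linear_coefficients(model)
    assert coef is not None
    phi0 = float(np.asarray(model.predict(background), dtype=float).mean())
    phi = coef * (X - background.mean(axis=0))
    return phi, phi0


def _permutation_shapley(
    predict, X: np.ndarray, background: np.ndarray,
    n_permutations: int, rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    n, d = X.shape
    m = background.shape[0]
    phi0 = float(np.asarray(predict(background), dtype=float).mean())
    phi = np.zeros((n, d))
    orderings: list[np.ndarray] = []
    while len(orderings) < n_permutations:  # antithetic pairs
        p = rng.permutation(d)
        orderings.append(p)
        if len(orderings) < n_permutations:
            orderings.append(p[::-1].copy())
    for order in orderings:
        Z = np.repeat(background[None, :, :], n, axis=0)  # (n, m, d)
        v_prev = np.full(n, phi0)
        for f in order:
            Z[:, :, f] = X[:, f][:, None]
            preds = np.asarray(predict(Z.reshape(n * m, d)), dtype=float)
            v = preds.reshape(n, m).mean(axis=1)
            phi[:, f] += v - v_prev
            v_prev = v
    return phi / len(orderings), phi0


def exact_shapley(predict, X, background, max_features: int = 12):
    """Brute-force Shapley values by full subset enumeration.

    The value of a coalition S is the background-mean prediction with the
    features in S taken from the explained row.  Cost is O(2^d); refuse
    beyond ``max_features``.
    """
    X, names = _as_array(X)
    background = np.asarray(background, dtype=float)
    n, d = X.shape
    if d > max_features:
        raise ValueError(f"exact enumeration refused for d={d} > {max_features}")
    m = background.shape[0]

    def value(row: np.ndarray, subset: tuple[int, ...]) -> float:
        Z = background.copy()
        Z[:, list(subset)] = row[list(subset)]
        return float(np.asarray(predict(Z), dtype=float).mean())

    phi0 = value(X[0], ())
    phi = np.zeros((n, d))
    feats = range(d)
    for i in range(n):
        cache: dict[tuple[int, ...], float] = {}

        def v(subset: tuple[int, ...], row=X[i]) -> float:
            if subset not in cache:
                cache[subset] = value(row, subset)
            return cache[subset]

        for j in feats:
            others = [f for f in feats if f != j]
            total = 0.0
            for k in range(d):
                w = factorial(k) * factorial(d - k - 1) / factorial(d)
                for S in combinations(others, k):
                    total += w * (v(tuple(sorted(S + (j,)))) - v(S))
            phi[i, j] = total
    return AttributionMatrix(phi=phi, phi0=phi0, feature_values=X, feature_names=names)


def compute_attributions(
    model,
    X,
    background=None,
    engine: str = "auto",
    n_permutations: int = 10,
    max_background: int = 64,
    seed: int = 0,
    check_additivity: bool = True,
    tolerance: float | None = None,
) -> AttributionMatrix:
    """Additive attributions for ``model`` on the rows of ``X``.

    ``background`` defaults to ``X`` itself (subsampled to ``max_background``
    rows for the permutation and exact engines).  After computation the
    additivity identity is validated row-wise against ``model.predict`` at
    ``tolerance`` relative to prediction scale.  The default tolerance is
    1e-6, except for the xgboost native engine whose contributions are
    emitted in float32 (1e-5: the identity holds exactly in the booster,
    but its storage precision rounds each term).
    """
    Xarr, names = _as_array(X)
    if engine == "auto":
        engine = _detect_engine(model)
    bg = Xarr if background is None else np.asarray(background, dtype=float)
    if bg.shape[0] > max_background:
        idx = np.random.default_rng(seed).choice(bg.shape[0], max_background, replace=False)
        bg = bg[np.sort(idx)]

    if engine == "xgboost_native":
        phi, phi0 = _xgboost_contribs(model, Xarr)
    elif engine == "lightgbm_native":
        phi, phi0 = _lightgbm_contribs(model, Xarr)
    elif engine == "linear":
        phi, phi0 = _linear_attributions(model, Xarr, bg)
    elif engine == "permutation":
        rng = np.random.default_rng(seed)
        phi, phi0 = _permutation_shapley(model.predict, Xarr, bg, n_permutations, rng)
    elif engine == "exact":
        result = exact_shapley(model.predict, Xarr, bg)
        phi, phi0 = result.phi, result.phi0
    else:
        raise ValueError(f"unknown attribution engine {engine!r}")

    result = AttributionMatrix(phi=phi, phi0=phi0, feature_values=Xarr,
                               feature_names=names)
    if check_additivity:
        if tolerance is None:
            tolerance = 1e-5 if engine == "xgboost_native" else 1e-6
        preds = np.asarray(model.predict(Xarr), dtype=float)
        gap = np.abs(result.predictions - preds)
        scale = max(1.0, float(np.abs(preds).max()))
        if gap.max() > tolerance * scale:
            raise AdditivityError(
                f"additivity identity violated: max row gap {gap.max():.3e} "
                f"exceeds {tolerance:.1e} x prediction scale ({engine} engine)"
            )
    return result


def importance_shares(A: AttributionMatrix) -> pd.DataFrame:
    """Mean |phi| per feature, percentage shares and ranks.

    share_j = 100 * mean_i|phi_ij| / sum_k mean_i|phi_ik|; ranks descend by
    share with ties broken alphabetically by feature name.
    """
    mean_abs = np.abs(A.phi).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        raise ValueError("all attributions are zero: shares undefined")
    table = pd.DataFrame({
        "feature": list(A.feature_names),
        "mean_abs_phi": mean_abs,
        "share_pct": 100.0 * mean_abs / total,
    })
    table = table.sort_values(
        ["mean_abs_phi", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def attribution_scatter(A: AttributionMatrix, feature: str) -> pd.DataFrame:
    """(x, phi) pairs for one feature, sorted by x; ties keep input order."""
    if feature not in A.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = A.feature_names.index(feature)
    df = pd.DataFrame({"x": A.feature_values[:, j], "phi": A.phi[:, j]})
    return df.sort_values("x", kind="stable").reset_index(drop=True)
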