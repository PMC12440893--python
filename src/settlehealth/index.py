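"""Composite Health Level Index construction.

The index pools all province-year rows, min-max normalises each health
indicator according to its direction attribute (higher-is-better vs
lower-is-better), weights indicators by their information content (entropy
weighting), and scores each row by TOPSIS relative closeness to the
column-wise ideal point.  The resulting Health Level Index (HLI) lies in
[0, 1], larger meaning healthier.

Also provides the surrounding preprocessing: derived settlement indicators
(road area per capita, sanitation vehicles per 10,000, population density,
urbanisation rate), per-unit linear interpolation of interior gaps in yearly
series, and a pairwise-correlation screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic import HEALTH_INDICATOR_DIRECTIONS

__all__ = [
    "EntropyTopsis",
    "DegenerateColumnWarning",
    "derive_indicators",
    "interpolate_series",
    "correlation_screen",
    "normalize_matrix",
    "entropy_weights",
    "topsis_closeness",
    "build_hli",
]


class DegenerateColumnWarning(UserWarning):
    """A constant indicator column carries no information; its weight is 0."""


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix of indicator values")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _direction_signs(directions, columns: list[str]) -> np.ndarray:
    """Map per-column direction tags to +1 (positive) / -1 (negative)."""
    if isinstance(directions, dict):
        missing = [c for c in columns if c not in directions]
        if missing:
            raise ValueError(f"missing direction tag for column(s) {missing}")
        tags = [directions[c] for c in columns]
    else:
        tags = list(directions)
        if len(tags) != len(columns):
            raise ValueError("one direction tag per column is required")
    signs = []
    for t in tags:
        if t in ("positive", "+", 1, +1):
            signs.append(1.0)
        elif t in ("negative", "-", -1):
            signs.append(-1.0)
        else:
            raise ValueError(f"unknown direction tag {t!r}")
    return np.array(signs)


def normalize_matrix(X, directions) -> np.ndarray:
    """Direction-aware min-max normalisation to [0, 1].

    Positive columns map min -> 0 and max -> 1; negative columns map
    max -> 0 and min -> 1.  A constant column (max == min) is set to 0
    everywhere with a warning: it carries no information and receives zero
    entropy weight downstream.
    """
    arr, cols = _as_matrix(X)
    if np.isnan(arr).any():
        raise ValueError("indicator matrix contains missing values")
    signs = _direction_signs(directions, cols)
    mn, mx = arr.min(axis=0), arr.max(axis=0)
    span = mx - mn
    degenerate = span == 0
    if degenerate.any():
        bad = [cols[j] for j in np.nonzero(degenerate)[0]]
        warnings.warn(
            f"constant indicator column(s) {bad}: normalised to 0, weight will be 0",
            DegenerateColumnWarning,
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    pos = (arr - mn) / safe
    neg = (mx - arr) / safe
    out = np.where(signs > 0, pos, neg)
    out[:, degenerate] = 0.0
    return out


@dataclass(frozen=True)
class EntropyWeights:
    proportions: np.ndarray
    entropies: np.ndarray
    divergences: np.ndarray
    weights: np.ndarray


def entropy_weights(Xn: np.ndarray) -> EntropyWeights:
    """Entropy weights from a normalised (nonnegative) matrix.

    r_ij = x'_ij / sum_i x'_ij; e_j = -(1/ln m) sum_i r_ij ln r_ij with the
    0*ln 0 = 0 convention; d_j = 1 - e_j; w_j = d_j / sum_k d_k.
    """
    Xn = np.asarray(Xn, dtype=float)
    if Xn.ndim != 2 or Xn.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if (Xn < 0).any():
        raise ValueError("normalised matrix must be nonnegative")
    m = Xn.shape[0]
    colsum = Xn.sum(axis=0)
    zero_col = colsum == 0
    r = Xn / np.where(zero_col, 1.0, colsum)
    r[:, zero_col] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    e = -rlogr.sum(axis=0) / np.log(m)
    e[zero_col] = 1.0  # a zero column is treated as maximally uninformative
    d = 1.0 - e
    # guard against tiny negative entropies from rounding
    d = np.where(np.abs(d) < 1e-15, 0.0, d)
    if d.sum() <= 0:
        raise ValueError("all indicator columns are uninformative (zero divergence)")
    w = d / d.sum()
    return EntropyWeights(proportions=r, entropies=e, divergences=d, weights=w)


@dataclass(frozen=True)
class TopsisResult:
    weighted: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    dist_pos: np.ndarray
    dist_neg: np.ndarray
    closeness: np.ndarray


def topsis_closeness(Xn: np.ndarray, weights: np.ndarray) -> TopsisResult:
    """TOPSIS relative closeness of each row to the column-wise ideal point.

    v_ij = w_j x'_ij; the ideal (anti-ideal) point is the column-wise max
    (min) of V; distances are Euclidean; closeness = D- / (D+ + D-).
    """
    Xn = np.asarray(Xn, dtype=float)
    w = np.asarray(weights, dtype=float)
    if Xn.shape[1] != w.shape[0]:
        raise ValueError("weight length must match the number of columns")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must sum to 1")
    V = Xn * w
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    d_pos = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_pos + d_neg
    if np.any(denom == 0):
        raise ValueError(
            "sample with zero distance to both ideal points; all columns degenerate"
        )
    return TopsisResult(
        weighted=V, ideal=ideal, anti_ideal=anti,
        dist_pos=d_pos, dist_neg=d_neg, closeness=d_neg / denom,
    )


class EntropyTopsis(BaseEstimator, TransformerMixin):
    """Entropy-weighted TOPSIS composite scorer.

    Parameters
    ----------
    directions : dict or sequence
        Direction tag per indicator column, ``"positive"`` (higher is better)
        or ``"negative"``.  A dict maps column names; a sequence is
        positional.

    Attributes (after ``fit``)
    --------------------------
    normalized_, proportions_, entropies_, divergences_, weights_,
    weighted_, ideal_, anti_ideal_, dist_pos_, dist_neg_, closeness_ :
        the full decision stack over the fitted (pooled) sample.
    """

    def __init__(self, directions=None):
        self.directions = directions

    def fit(self, X, y=None):
        arr, cols = _as_matrix(X)
        if arr.shape[0] < 2:
            raise ValueError("need at least two samples")
        directions = self.directions
        if directions is None:
            directions = {c: HEALTH_INDICATOR_DIRECTIONS[c] for c in cols} \
                if all(c in HEALTH_INDICATOR_DIRECTIONS for c in cols) else None
        if directions is None:
            raise ValueError("directions must be provided for these columns")
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.signs_ = _direction_signs(directions, cols)
        self.min_ = arr.min(axis=0)
        self.max_ = arr.max(axis=0)
        self.normalized_ = normalize_matrix(pd.DataFrame(arr, columns=cols), directions)
        ew = entropy_weights(self.normalized_)
        self.proportions_ = ew.proportions
        self.entropies_ = ew.entropies
        self.divergences_ = ew.divergences
        self.weights_ = ew.weights
        ts = topsis_closeness(self.normalized_, self.weights_)
        self.weighted_ = ts.weighted
        self.ideal_ = ts.ideal
        self.anti_ideal_ = ts.anti_ideal
        self.dist_pos_ = ts.dist_pos
        self.dist_neg_ = ts.dist_neg
        self.closeness_ = ts.closeness
        return self

    def transform(self, X) -> np.ndarray:
        """Closeness scores for (possibly new) rows under the fitted stack.

        New rows are normalised with the fitted min/max (clipped to [0, 1])
        and scored against the fitted ideal points, so scores of the fitted
        sample are reproduced exactly.
        """
        check_is_fitted(self, "weights_")
        arr, cols = _as_matrix(X)
        if arr.shape[1] != len(self.feature_names_in_):
            raise ValueError("column count differs from the fitted matrix")
        span = self.max_ - self.min_
        safe = np.where(span == 0, 1.0, span)
        pos = (arr - self.min_) / safe
        xn = np.clip(np.where(self.signs_ > 0, pos, 1.0 - pos), 0.0, 1.0)
        xn[:, span == 0] = 0.0
        V = xn * self.weights_
        d_pos = np.sqrt(((V - self.ideal_) ** 2).sum(axis=1))
        d_neg = np.sqrt(((V - self.anti_ideal_) ** 2).sum(axis=1))
        return d_neg / (d_pos + d_neg)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).closeness_


def build_hli(
    panel: pd.DataFrame,
    indicator_columns=None,
    directions=None,
    column: str = "HLI",
) -> tuple[pd.DataFrame, dict]:
    """Append a composite HLI column to a panel; return (panel, report).

    The scorer is fitted on the pooled sample (all rows at once), so one
    weight vector describes the whole panel.  The report carries weights,
    entropies and ideal points for serialisation.
    """
    if indicator_columns is None:
        indicator_columns = [c for c in HEALTH_INDICATOR_DIRECTIONS if c in panel.columns]
        if len(indicator_columns) != len(HEALTH_INDICATOR_DIRECTIONS):
            missing = set(HEALTH_INDICATOR_DIRECTIONS) - set(panel.columns)
            raise ValueError(f"panel lacks health indicator column(s) {sorted(missing)}")
    if directions is None:
        directions = {c: HEALTH_INDICATOR_DIRECTIONS[c] for c in indicator_columns}
    X = panel[list(indicator_columns)]
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)].tolist()
        raise ValueError(f"missing indicator values in rows {bad[:10]}")
    model = EntropyTopsis(directions=directions).fit(X)
    out = panel.copy()
    out[column] = model.closeness_
    report = {
        "indicators": list(indicator_columns),
        "directions": {c: directions[c] for c in indicator_columns},
        "weights": dict(zip(indicator_columns, model.weights_.tolist())),
        "entropies": dict(zip(indicator_columns, model.entropies_.tolist())),
        "ideal": model.ideal_.tolist(),
        "anti_ideal": model.anti_ideal_.tolist(),
    }
    return out, report


# ---------------------------------------------------------------------------
# preprocessing around the index


def derive_indicators(raw: pd.DataFrame) -> pd.DataFrame:
    """Derived settlement indicators from raw provincial totals.

    RAPC = road area / resident population (m^2 per person);
    NSV  = sanitation vehicles / population * 10,000;
    PD   = population / administrative area (persons per km^2);
    UR   = urban population / population, in percent.
    """
    required = ["road_area", "resident_pop_year_end", "sanitation_vehicles",
                "admin_area", "urban_pop"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table lacks column(s) {missing}")
    pop = raw["resident_pop_year_end"]
    for col in ("resident_pop_year_end", "admin_area"):
        bad = raw.index[raw[col] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive {col} in rows {bad[:10]}")
    return pd.DataFrame(
        {
            "RAPC": raw["road_area"] / pop,
            "NSV": raw["sanitation_vehicles"] / pop * 10_000,
            "PD": pop / raw["admin_area"],
            "UR": raw["urban_pop"] / pop * 100.0,
        },
        index=raw.index,
    )


def interpolate_series(
    panel: pd.DataFrame,
    value: str,
    unit: str = "province",
    year: str = "year",
) -> pd.DataFrame:
    """Fill interior gaps (NaN) in a per-unit yearly series by straight lines.

    Each unit needs at least two observed anchor years, and gaps before the
    first or after the last anchor are refused (interpolation only, never
    extrapolation).  Anchor values are returned untouched.
    """
    out = panel.copy()
    for uid, grp in panel.groupby(unit, sort=False):
        grp = grp.sort_values(year)
        y = grp[value].to_numpy(dtype=float)
        t = grp[year].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            raise ValueError(f"unit {uid!r} has fewer than 2 anchor years for {value!r}")
        first, last = np.nonzero(obs)[0][[0, -1]]
        if first > 0 or last < len(y) - 1:
            raise ValueError(
                f"unit {uid!r}: gap outside the anchor span for {value!r} "
                "(edge gaps cannot be interpolated)"
            )
        filled = np.interp(t, t[obs], y[obs])
        filled[obs] = y[obs]
        out.loc[grp.index, value] = filled
    return out


def correlation_screen(X, limit: float = 0.6) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations with a multicollinearity flag list.

    Pairs with |r| >= limit are flagged (a warning for the analyst, not a
    failure).  Constant columns are rejected: their correlation is undefined.
    """
    arr, cols = _as_matrix(X)
    if arr.shape[1] < 2:
        raise ValueError("need at least two columns")
    if (arr.std(axis=0) == 0).any():
        bad = [cols[j] for j in np.nonzero(arr.std(axis=0) == 0)[0]]
        raise ValueError(f"constant column(s) {bad}: correlation undefined")
    r = np.corrcoef(arr, rowvar=False)
    corr = pd.DataFrame(r, index=cols, columns=cols)
    flags = [
        (cols[i], cols[j], float(r[i, j]))
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(r[i, j]) >= limit
    ]
    return corr, flags
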