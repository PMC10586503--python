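"""Entropy-weighted TOPSIS construction of the supply-capacity index.

The index chain is: direction-aware min-max normalization of the pooled
unit-year x indicator matrix, entropy weighting (high-dispersion indicators
earn more weight), weighting of the normalized matrix, per-indicator
positive/negative ideal points, Euclidean distances D+ / D- to those ideals,
and the closeness coefficient

    Ci = D- / (D- + D+)  in [0, 1],

read as supply capacity (1 = ideal).  Negative-direction indicators are
reversed during normalization, so every column of the normalized matrix is
benefit-oriented and the ideal points are plain column extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ID_COLUMNS, IndicatorSchema, PanelTable

__all__ = [
    "NormalizedMatrix",
    "WeightVector",
    "IdealPoints",
    "SupplyIndex",
    "minmax_normalize",
    "entropy_weights",
    "topsis_scores",
    "build_index_panel",
]


@dataclass
class NormalizedMatrix:
    """m x n matrix of direction-adjusted values in [0, 1]."""

    values: np.ndarray
    indicator_ids: list[str]
    pooling: str = "pooled"
    index: pd.DataFrame | None = None  # unit_id/region_id/year rows, optional

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("normalized matrix must be 2-D")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValueError("normalized values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class WeightVector:
    weights: np.ndarray
    indicator_ids: list[str]
    source: str  # {"entropy", "fixed"}

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        self.weights = w

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.indicator_ids, name="weight")


@dataclass
class IdealPoints:
    z_plus: np.ndarray
    z_minus: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.z_minus > self.z_plus + 1e-15):
            raise ValueError("negative ideal exceeds positive ideal")


@dataclass
class SupplyIndex:
    """Per-observation TOPSIS result: distances and closeness coefficient."""

    d_plus: np.ndarray
    d_minus: np.ndarray
    ci: np.ndarray
    ideals: IdealPoints | None = None
    index: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        base = (
            self.index.copy()
            if self.index is not None
            else pd.DataFrame(index=range(len(self.ci)))
        )
        base["d_plus"] = self.d_plus
        base["d_minus"] = self.d_minus
        base["ci"] = self.ci
        return base


def _normalize_columns(x: np.ndarray, directions: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    out = np.empty_like(x, dtype=float)
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"constant indicator column(s) at positions {np.flatnonzero(constant).tolist()}; "
            "normalized to 0.5 (entropy weight will be 0)",
            stacklevel=3,
        )
    safe = np.where(constant, 1.0, span)
    pos = (x - lo) / safe
    neg = (hi - x) / safe
    out = np.where(directions[None, :] > 0, pos, neg)
    out[:, constant] = 0.5
    return out


def minmax_normalize(
    panel: PanelTable, schema: IndicatorSchema | None = None, pooling: str = "pooled"
) -> NormalizedMatrix:
    """Direction-aware min-max normalization of the panel's indicator matrix.

    With ``pooling="pooled"`` extrema are taken over all unit-years at once
    (a single scale for the whole study window); ``"per_year"`` rescales
    within each calendar year.
    """
    schema = schema or panel.schema
    if pooling not in ("pooled", "per_year"):
        raise ValueError(f"unknown pooling {pooling!r}")
    x = panel.data[schema.ids].to_numpy(dtype=float)
    directions = schema.directions
    if pooling == "pooled":
        values = _normalize_columns(x, directions)
    else:
        values = np.empty_like(x)
        for year in panel.years:
            mask = (panel.data["year"] == year).to_numpy()
            values[mask] = _normalize_columns(x[mask], directions)
    return NormalizedMatrix(
        values=values,
        indicator_ids=schema.ids,
        pooling=pooling,
        index=panel.data[list(ID_COLUMNS)].copy(),
    )


def entropy_weights(norm: NormalizedMatrix) -> WeightVector:
    """Entropy weights from the normalized matrix.

    p_ij = x'_ij / sum_i x'_ij (0/0 -> 0); e_j = -(1/ln m) sum_i p_ij ln p_ij
    with 0 ln 0 := 0; d_j = 1 - e_j; w_j = d_j / sum d_j.  An all-zero column
    carries no information: e_j := 1, weight 0.
    """
    x = norm.values
    m = x.shape[0]
    if m < 2:
        raise ValueError("entropy weights need at least 2 observations")
    colsum = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(colsum > 0, x / np.where(colsum == 0, 1.0, colsum), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    e = np.where(colsum > 0, e, 1.0)
    d = 1.0 - e
    d = np.where(d < 0, 0.0, d)  # guard tiny negative rounding
    if d.sum() == 0:
        raise ValueError("all indicator columns are constant; entropy weights undefined")
    return WeightVector(weights=d / d.sum(), indicator_ids=list(norm.indicator_ids), source="entropy")


def topsis_scores(norm: NormalizedMatrix, weights: WeightVector) -> SupplyIndex:
    """Closeness coefficients from the weighted normalized matrix.

    z_ij = w_j x'_ij; ideal points are column extrema of z; distances are
    Euclidean.  Weights enter once, in z (not again inside the distance).
    """
    if list(norm.indicator_ids) != list(weights.indicator_ids):
        raise ValueError("indicator order mismatch between matrix and weights")
    z = norm.values * weights.weights[None, :]
    z_plus = z.max(axis=0)
    z_minus = z.min(axis=0)
    d_plus = np.sqrt(((z - z_plus[None, :]) ** 2).sum(axis=1))
    d_minus = np.sqrt(((z - z_minus[None, :]) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if np.any(denom == 0):
        raise ValueError(
            "degenerate observation with D+ + D- = 0 (all weighted columns constant)"
        )
    ci = d_minus / denom
    return SupplyIndex(
        d_plus=d_plus,
        d_minus=d_minus,
        ci=ci,
        ideals=IdealPoints(z_plus=z_plus, z_minus=z_minus),
        index=norm.index,
    )


def build_index_panel(
    panel: PanelTable,
    schema: IndicatorSchema | None = None,
    weight_mode: str = "entropy",
    pooling: str = "pooled",
) -> tuple[pd.DataFrame, WeightVector]:
    """Full index chain: normalize -> weight -> TOPSIS, keyed by (unit, year).

    Returns the index frame (unit_id, region_id, year, d_plus, d_minus, ci)
    and the weight vector actually used.  ``weight_mode="fixed"`` takes the
    schema's published weights instead of entropy weights.
    """
    schema = schema or panel.schema
    norm = minmax_normalize(panel, schema, pooling=pooling)
    if weight_mode == "entropy":
        w = entropy_weights(norm)
    elif weight_mode == "fixed":
        fixed = schema.fixed_weights
        w = WeightVector(weights=fixed / fixed.sum(), indicator_ids=schema.ids, source="fixed")
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    scores = topsis_scores(norm, w)
    return scores.frame(), w
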