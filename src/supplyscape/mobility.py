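"""Level mobility of the supply index: Markov chains and spatial conditioning.

Pooled quartiles cut the index into four capacity levels (I low ... IV high);
year-over-year level transitions are tallied into a 4x4 count matrix and the
transition probabilities are the row-wise maximum-likelihood estimates
P_ij = n_ij / n_i.  Conditioning each transition on the quartile level of the
unit's spatial lag (row-standardized neighborhood average) in the origin year
yields four conditional matrices — the spatial Markov chain — whose counts
partition the unconditional counts exactly.  Global Moran's I with normality
or permutation inference tests whether the cross-sections are spatially
clustered at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SpatialWeights

__all__ = [
    "LEVEL_LABELS",
    "LevelScheme",
    "TransitionCounts",
    "TransitionMatrix",
    "SpatialTransitionSet",
    "MoranResult",
    "classify_levels",
    "count_transitions",
    "mle_transition_matrix",
    "spatial_lag",
    "spatial_markov",
    "morans_i",
    "morans_i_by_year",
]

LEVEL_LABELS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class LevelScheme:
    """Quartile cut points with the boundary rule I: c<=Q1, ..., IV: c>Q3.

    Quantiles use linear interpolation between order statistics, the
    convention under which 610 distinct pooled values split 153/152/152/153.
    """

    q1: float
    q2: float
    q3: float

    def assign(self, values) -> np.ndarray:
        """Integer levels 1..4 per the boundary rule."""
        v = np.asarray(values, dtype=float)
        return (
            1 + (v > self.q1).astype(int) + (v > self.q2).astype(int) + (v > self.q3).astype(int)
        )


@dataclass
class TransitionCounts:
    counts: np.ndarray  # 4x4 integer matrix, rows = origin level

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (4, 4) or np.any(c < 0):
            raise ValueError("counts must be a nonnegative 4x4 matrix")
        self.counts = c.astype(int)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionMatrix:
    probabilities: np.ndarray
    counts: TransitionCounts

    @property
    def defined_rows(self) -> np.ndarray:
        return self.counts.row_totals > 0

    def row(self, i: int) -> np.ndarray:
        if not self.defined_rows[i]:
            raise ValueError(f"transition row {LEVEL_LABELS[i]} is undefined (no observations)")
        return self.probabilities[i]

    def frame(self, percent: bool = True) -> pd.DataFrame:
        p = self.probabilities * (100 if percent else 1)
        out = pd.DataFrame(p, index=list(LEVEL_LABELS), columns=list(LEVEL_LABELS))
        out.insert(0, "n", self.counts.row_totals)
        out.index.name = "type"
        return out


@dataclass
class SpatialTransitionSet:
    """One conditional transition matrix per spatial-lag level."""

    conditional: dict[str, TransitionMatrix]
    unconditional: TransitionCounts

    def __post_init__(self) -> None:
        total = sum(m.counts.counts for m in self.conditional.values())
        if not np.array_equal(total, self.unconditional.counts):
            raise ValueError("conditional counts do not partition the unconditional counts")

    def frame(self, percent: bool = True) -> pd.DataFrame:
        parts = []
        for lag, matrix in self.conditional.items():
            f = matrix.frame(percent=percent).reset_index()
            f.insert(0, "adjacent_type", lag)
            parts.append(f)
        return pd.concat(parts, ignore_index=True)


@dataclass
class MoranResult:
    I: float
    expected: float
    sd: float
    z: float
    p: float
    method: str = "normality"
    n_permutations: int | None = None

    def stars(self) -> str:
        return "***" if self.p < 0.01 else "**" if self.p < 0.05 else "*" if self.p < 0.10 else ""


# ---------------------------------------------------------------------------


def classify_levels(index_panel: pd.DataFrame, column: str = "ci") -> tuple[pd.DataFrame, LevelScheme]:
    """Quartile level classification on the pooled unit-year values."""
    values = index_panel[column].to_numpy(dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 pooled observations for quartiles")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    if not (q1 < q2 < q3):
        warnings.warn("degenerate quartiles (heavy ties); levels may collapse", stacklevel=2)
    scheme = LevelScheme(q1=float(q1), q2=float(q2), q3=float(q3))
    out = index_panel.copy()
    out["level"] = scheme.assign(values)
    return out, scheme


def count_transitions(levels: pd.DataFrame, column: str = "level") -> TransitionCounts:
    """Pooled year-over-year level transition counts.

    One transition per unit per consecutive year pair, pooled over the
    whole observation window: 61 units x 10 years yield 61 x 9 = 549.
    """
    years = sorted(levels["year"].unique())
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError(f"years are not consecutive: {years}")
    wide = levels.pivot(index="unit_id", columns="year", values=column).to_numpy(dtype=float)
    if np.isnan(wide).any():
        raise ValueError("missing (unit, year) level observations")
    origin = wide[:, :-1].astype(int).ravel() - 1
    dest = wide[:, 1:].astype(int).ravel() - 1
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (origin, dest), 1)
    return TransitionCounts(counts=counts)


def mle_transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Row-wise MLE P_ij = n_ij / n_i; empty rows are NaN (undefined)."""
    totals = counts.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts.counts / totals[:, None]
    p[totals == 0] = np.nan
    return TransitionMatrix(probabilities=p, counts=counts)


def spatial_lag(
    index_panel: pd.DataFrame,
    weights: SpatialWeights,
    scheme: LevelScheme,
    column: str = "ci",
) -> pd.DataFrame:
    """Neighborhood-average index per unit-year, classified on the same cuts.

    Requires row-standardized weights so the lag is a weighted average of
    neighbor values; lag levels reuse the pooled unit-level cut points.
    """
    if not weights.row_standardized:
        raise ValueError("spatial lag requires row-standardized weights")
    units = sorted(index_panel["unit_id"].unique())
    if set(units) != set(weights.units):
        raise ValueError("unit sets of index panel and weights differ")
    w = weights.reorder(units).matrix
    out = []
    for year, sub in index_panel.groupby("year"):
        sub = sub.set_index("unit_id").loc[units]
        lag = w @ sub[column].to_numpy(dtype=float)
        out.append(
            pd.DataFrame(
                {"unit_id": units, "year": year, "lag": lag, "lag_level": scheme.assign(lag)}
            )
        )
    return pd.concat(out, ignore_index=True)


def spatial_markov(levels: pd.DataFrame, lag_levels: pd.DataFrame) -> SpatialTransitionSet:
    """Transition matrices conditioned on the origin-year spatial-lag level."""
    merged = levels.merge(lag_levels[["unit_id", "year", "lag_level"]], on=["unit_id", "year"])
    if len(merged) != len(levels):
        raise ValueError("level and lag series are not aligned on (unit, year)")
    unconditional = count_transitions(merged)

    years = sorted(merged["year"].unique())
    lvl = merged.pivot(index="unit_id", columns="year", values="level").loc[:, years].to_numpy(int)
    lag = merged.pivot(index="unit_id", columns="year", values="lag_level").loc[:, years].to_numpy(int)
    conditional: dict[str, TransitionMatrix] = {}
    for s, label in enumerate(LEVEL_LABELS, start=1):
        counts = np.zeros((4, 4), dtype=int)
        mask = lag[:, :-1] == s
        np.add.at(counts, (lvl[:, :-1][mask] - 1, lvl[:, 1:][mask] - 1), 1)
        conditional[label] = mle_transition_matrix(TransitionCounts(counts=counts))
    return SpatialTransitionSet(conditional=conditional, unconditional=unconditional)


# ---------------------------------------------------------------------------
# Global Moran's I


def morans_i(
    values,
    weights: SpatialWeights,
    method: str = "normality",
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Global Moran's I with one-sided (clustering) inference.

    I = n * sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S0 * sum_i (x_i - xbar)^2),
    E(I) = -1/(n-1).  ``method="normality"`` uses the closed-form variance
    under the normal-approximation null; ``"permutation"`` adds a Monte
    Carlo p-value from random relabelings of the units.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if n != weights.n:
        raise ValueError("value vector and weight matrix sizes differ")
    w = weights.matrix
    if weights.isolated_units():
        raise ValueError(f"isolated unit(s): {weights.isolated_units()}")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("zero variance: Moran's I undefined")
    s0 = w.sum()
    observed = float(n / s0 * (z @ w @ z) / ss)

    e_i = -1.0 / (n - 1)
    # normality-assumption moments
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i * e_i
    sd = float(np.sqrt(var))
    zscore = (observed - e_i) / sd
    p_norm = float(stats.norm.sf(zscore))

    if method == "normality":
        return MoranResult(I=observed, expected=e_i, sd=sd, z=zscore, p=p_norm)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perms = np.array([gen.permutation(z) for _ in range(n_permutations)])
    sims = n / s0 * np.einsum("ki,ij,kj->k", perms, w, perms) / ss
    p_perm = (1 + int((sims >= observed).sum())) / (n_permutations + 1)
    return MoranResult(
        I=observed,
        expected=e_i,
        sd=sd,
        z=zscore,
        p=float(p_perm),
        method="permutation",
        n_permutations=n_permutations,
    )


def morans_i_by_year(
    index_panel: pd.DataFrame,
    weights: SpatialWeights,
    column: str = "ci",
    method: str = "normality",
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One Moran's I row per year (I, E(I), SD(I), z, p, stars)."""
    units = sorted(index_panel["unit_id"].unique())
    w = weights.reorder(units) if list(weights.units) != units else weights
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for year, sub in index_panel.groupby("year"):
        x = sub.set_index("unit_id").loc[units, column].to_numpy()
        res = morans_i(x, w, method=method, n_permutations=n_permutations, rng=gen)
        rows.append(
            {
                "year": int(year),
                "I": res.I,
                "E(I)": res.expected,
                "SD(I)": res.sd,
                "z": res.z,
                "p": res.p,
                "stars": res.stars(),
            }
        )
    return pd.DataFrame(rows)
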