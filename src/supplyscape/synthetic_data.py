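"""Seeded generators of study-shaped inputs, plus packaged published tables.

The generator emulates the statistical shape of the study panel: 61 county
units in three ordered regional blocks (21/20/20) observed 2010-2019, a
queen-contiguity lattice adjacency standing in for county contiguity, a
multi-indicator supply panel with regional level gradients, upward yearly
trends and a spatially autocorrelated (SAR-structured) unit effect shared
across indicators, and a covariate panel generated from a two-way-effects
log-linear model with a known elasticity vector.

``fixtures()`` returns machine-readable copies of the published summary
tables (indicator weights, transition-matrix layout, yearly Moran and Gini
series).  The transition-count rows are not printed at count level; they
are recovered at import time by exhaustive search for the integer
composition of each printed row total whose percentages round to the
printed two-decimal cells (see :func:`derive_count_row`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    IndicatorSchema,
    PanelTable,
    RegionPartition,
    SpatialWeights,
    panel_from_frame,
    row_standardize,
    table1_schema,
)
from .determinants import COVARIATES

__all__ = [
    "SimConfig",
    "FixtureSet",
    "make_lattice_weights",
    "make_partition",
    "simulate_index_panel",
    "simulate_determinants_panel",
    "fixtures",
    "derive_count_row",
]

#: published elasticities of the five determinants (econ, urba, tran, open, empl)
TRUE_ELASTICITIES = (0.165, 0.192, 0.295, 0.094, 0.077)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic study.

    Defaults reproduce the study conditions: 61 units in blocks of
    21/20/20, years 2010-2019, spatial dependence rho = 0.6, regional
    baseline gradient and positive trends, and the published elasticity
    vector for the determinants experiment.
    """

    n_units: int = 61
    region_sizes: tuple[int, ...] = (21, 20, 20)
    region_names: tuple[str, ...] = ("north", "southwest", "southeast")
    year_start: int = 2010
    year_end: int = 2019
    lattice_shape: tuple[int, int] = (8, 8)
    rho: float = 0.6
    region_baselines: tuple[float, ...] = (1.7, 1.0, 1.3)
    trend_slopes: tuple[float, ...] = (0.09, 0.07, 0.08)
    unit_effect_sd: float = 0.25
    indicator_noise_sd: float = 0.20
    elasticities: tuple[float, ...] = TRUE_ELASTICITIES
    regression_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.region_sizes) != self.n_units:
            raise ValueError("region sizes must sum to n_units")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if min(self.unit_effect_sd, self.indicator_noise_sd, self.regression_noise_sd) < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.lattice_shape[0] * self.lattice_shape[1] < self.n_units:
            raise ValueError("lattice too small for n_units")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def unit_ids(self) -> list[str]:
        return [f"c{i:02d}" for i in range(1, self.n_units + 1)]


def make_partition(config: SimConfig) -> RegionPartition:
    """Contiguous blocks of lattice cells assigned to the ordered regions."""
    assignment: dict[str, str] = {}
    cursor = 0
    for name, size in zip(config.region_names, config.region_sizes):
        for uid in config.unit_ids[cursor : cursor + size]:
            assignment[uid] = name
        cursor += size
    return RegionPartition(assignment=assignment, region_order=config.region_names)


def _queen_adjacency(rows: int, cols: int, keep: int) -> np.ndarray:
    w = np.zeros((keep, keep))
    for a in range(keep):
        ra, ca = divmod(a, cols)
        for b in range(a + 1, keep):
            rb, cb = divmod(b, cols)
            if max(abs(ra - rb), abs(ca - cb)) == 1:
                w[a, b] = w[b, a] = 1.0
    return w


def _connected(w: np.ndarray) -> bool:
    n = w.shape[0]
    seen = {0}
    queue = deque([0])
    while queue:
        i = queue.popleft()
        for j in np.flatnonzero(w[i] > 0):
            if j not in seen:
                seen.add(int(j))
                queue.append(int(j))
    return len(seen) == n


def make_lattice_weights(config: SimConfig, standardize: bool = True) -> SpatialWeights:
    """Queen contiguity over the first n_units cells of a rectangular lattice."""
    rows, cols = config.lattice_shape
    w = _queen_adjacency(rows, cols, config.n_units)
    if not _connected(w):
        raise ValueError("selected lattice cells form a disconnected graph")
    sw = SpatialWeights(units=config.unit_ids, matrix=w)
    return row_standardize(sw) if standardize else sw


def _sar_unit_effect(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """u = (I - rho W)^-1 eta: spatially autocorrelated unit effect."""
    w = make_lattice_weights(config, standardize=True).matrix
    eta = rng.normal(0.0, config.unit_effect_sd, size=config.n_units)
    return np.linalg.solve(np.eye(config.n_units) - config.rho * w, eta)


def simulate_index_panel(
    config: SimConfig | None = None,
    schema: IndicatorSchema | None = None,
    rng: np.random.Generator | None = None,
) -> PanelTable:
    """Synthetic indicator panel with gradients, trends and spatial structure.

    Each indicator j of unit i in year t is
    ``scale_j * (baseline_r(i) + trend_r(i) * (t - t0) + u_i + eps_ijt)``
    with u the shared SAR unit effect; the single negative-direction
    indicator is generated on a reversed latent scale (declining over time,
    low where supply is high).  Values are clipped to stay positive.
    """
    config = config or SimConfig()
    schema = schema or table1_schema()
    rng = rng or np.random.default_rng(config.seed)
    partition = make_partition(config)

    region_index = {name: r for r, name in enumerate(config.region_names)}
    baselines = np.array(
        [config.region_baselines[region_index[partition.assignment[u]]] for u in config.unit_ids]
    )
    trends = np.array(
        [config.trend_slopes[region_index[partition.assignment[u]]] for u in config.unit_ids]
    )
    u = _sar_unit_effect(config, rng)

    years = np.array(config.years)
    t = years - years[0]
    latent = baselines[:, None] + trends[:, None] * t[None, :] + u[:, None]  # units x years

    # deterministic per-indicator scales spread over an order of magnitude,
    # mimicking the heterogeneous units of the raw yearbook indicators
    n_ind = len(schema)
    scales = np.geomspace(0.5, 5.0, n_ind)
    latent_ceiling = latent.max() + 1.0  # reversal point for the cost indicator

    records = []
    for ui, uid in enumerate(config.unit_ids):
        for ti, year in enumerate(years):
            row: dict = {
                "unit_id": uid,
                "region_id": partition.assignment[uid],
                "year": int(year),
            }
            eps = rng.normal(0.0, config.indicator_noise_sd, size=n_ind)
            for j, spec in enumerate(schema):
                core = latent[ui, ti]
                if spec.direction < 0:
                    core = latent_ceiling - core  # declining, low where supply high
                row[spec.id] = float(scales[j] * max(core + eps[j], 0.01))
            records.append(row)
    return panel_from_frame(pd.DataFrame.from_records(records), schema)


def simulate_determinants_panel(
    config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Balanced panel from Y_it = a_i + l_t + sum_n g_n X_itn + e_it.

    Unit effects a, year effects l and covariates X are standard normal;
    e ~ N(0, regression_noise_sd^2).  Columns are already on the log scale
    the determinants module expects (``y`` plus the five covariates).
    """
    config = config or SimConfig()
    rng = rng or np.random.default_rng(config.seed)
    n, T, k = config.n_units, len(config.years), len(COVARIATES)
    gamma = np.asarray(config.elasticities, dtype=float)
    X = rng.standard_normal((n, T, k))
    alpha = rng.standard_normal(n)
    lam = rng.standard_normal(T)
    eps = rng.normal(0.0, config.regression_noise_sd, size=(n, T))
    Y = alpha[:, None] + lam[None, :] + X @ gamma + eps

    idx = pd.MultiIndex.from_product(
        [config.unit_ids, config.years], names=["unit_id", "year"]
    )
    out = pd.DataFrame(X.reshape(n * T, k), columns=list(COVARIATES), index=idx)
    out.insert(0, "y", Y.reshape(n * T))
    return out.reset_index()


# ---------------------------------------------------------------------------
# Packaged published tables


def derive_count_row(total: int, percents: list[float]) -> tuple[int, ...]:
    """Unique integer composition of ``total`` matching rounded percentages.

    For each cell, candidate counts are those whose percentage of the row
    total rounds (half-up at 2 decimals) to the printed value; the search
    then walks the (tiny) candidate product for compositions summing to the
    row total and requires uniqueness.
    """
    candidates = []
    for pct in percents:
        cands = [
            c
            for c in range(total + 1)
            if round(100.0 * c / total + 1e-9, 2) == round(pct, 2)
        ]
        if not cands:
            raise ValueError(f"no count of {total} rounds to {pct}%")
        candidates.append(cands)

    solutions: list[tuple[int, ...]] = []

    def walk(pos: int, acc: list[int], remaining: int) -> None:
        if pos == len(candidates):
            if remaining == 0:
                solutions.append(tuple(acc))
            return
        for c in candidates[pos]:
            if c <= remaining:
                walk(pos + 1, acc + [c], remaining - c)

    walk(0, [], total)
    if len(solutions) != 1:
        raise ValueError(f"composition not unique for total {total}: {solutions}")
    return solutions[0]


_TABLE3_PERCENTS = {
    "I": (152, (60.53, 32.89, 3.95, 2.63)),
    "II": (150, (12.67, 46.00, 35.33, 6.00)),
    "III": (137, (2.19, 5.11, 59.12, 33.58)),
    "IV": (110, (2.73, 4.55, 9.09, 83.64)),
}

_TABLE4 = pd.DataFrame(
    {
        "year": list(range(2010, 2020)),
        "I": [0.324, 0.213, 0.116, 0.124, 0.147, 0.223, 0.358, 0.290, 0.252, 0.394],
        "E(I)": [-0.017] * 10,
        "SD(I)": [0.096, 0.099, 0.100, 0.100, 0.099, 0.100, 0.099, 0.099, 0.099, 0.098],
        "z": [3.530, 2.315, 1.319, 1.405, 1.655, 2.411, 3.771, 3.092, 2.715, 4.175],
        "p": [0.000, 0.010, 0.094, 0.080, 0.049, 0.008, 0.000, 0.001, 0.003, 0.000],
    }
)

_TABLE6_COLUMNS = [
    "year",
    "overall",
    "north-southwest",
    "north-southeast",
    "southwest-southeast",
    "within_north",
    "within_southwest",
    "within_southeast",
    "contrib_within",
    "contrib_between",
    "contrib_transvariation",
]

_TABLE6_ROWS = [
    (2010, 0.2859, 0.3231, 0.3118, 0.2273, 0.3287, 0.2571, 0.1814, 32.11, 27.96, 39.94),
    (2011, 0.4698, 0.4901, 0.5317, 0.4451, 0.4547, 0.4534, 0.2711, 30.83, 39.59, 29.59),
    (2012, 0.2108, 0.1735, 0.2206, 0.2491, 0.1116, 0.2093, 0.2733, 31.91, 15.89, 52.21),
    (2013, 0.1765, 0.1510, 0.2251, 0.1751, 0.1617, 0.1015, 0.2120, 30.15, 39.96, 29.89),
    (2014, 0.1493, 0.1234, 0.1564, 0.1701, 0.1004, 0.1384, 0.1940, 32.76, 21.71, 45.53),
    (2015, 0.1677, 0.1190, 0.2088, 0.2079, 0.0788, 0.1416, 0.2266, 29.03, 49.43, 21.54),
    (2016, 0.1681, 0.0921, 0.2318, 0.2373, 0.0667, 0.1105, 0.2407, 26.37, 55.66, 17.97),
    (2017, 0.1537, 0.1138, 0.1866, 0.1836, 0.0780, 0.1268, 0.2116, 29.87, 45.55, 24.58),
    (2018, 0.1297, 0.1021, 0.1450, 0.1499, 0.0727, 0.1119, 0.1795, 31.66, 33.72, 34.61),
    (2019, 0.1107, 0.0966, 0.1244, 0.1199, 0.0751, 0.0975, 0.1358, 31.32, 36.65, 32.03),
]


@dataclass
class FixtureSet:
    """Machine-readable copies of the published summary tables."""

    table1: IndicatorSchema
    table3_counts: pd.DataFrame
    table4_moran: pd.DataFrame
    table6_gini: pd.DataFrame

    def __post_init__(self) -> None:
        weights = self.table1.fixed_weights
        if abs(weights.sum() - 1.0) > 1e-3:
            raise ValueError("fixture weights do not sum to 1")
        yearly = self.table6_gini.drop(columns="year")
        # published Mean row must agree with the yearly column means; percent
        # columns are printed at 2 decimals, Gini columns at 4
        means = yearly.mean().to_numpy()
        tol = np.where(_TABLE6_MEAN_ROW > 1.0, 5e-3, 5e-5)
        if np.any(np.abs(means - _TABLE6_MEAN_ROW) > tol):
            raise ValueError("Gini Mean row inconsistent with yearly values")


_TABLE6_MEAN_ROW = np.array(
    [0.2022, 0.1785, 0.2342, 0.2165, 0.1528, 0.1748, 0.2126, 30.60, 36.61, 32.79]
)


def table6_mean_row() -> pd.Series:
    """The published Mean row of the yearly Gini table."""
    return pd.Series(_TABLE6_MEAN_ROW, index=_TABLE6_COLUMNS[1:])


def fixtures() -> FixtureSet:
    rows = []
    for level, (total, percents) in _TABLE3_PERCENTS.items():
        counts = derive_count_row(total, list(percents))
        rows.append(
            {
                "type": level,
                "n": total,
                **{lbl: c for lbl, c in zip(("I", "II", "III", "IV"), counts)},
            }
        )
    table3 = pd.DataFrame(rows)
    table6 = pd.DataFrame(_TABLE6_ROWS, columns=_TABLE6_COLUMNS)
    return FixtureSet(
        table1=table1_schema(),
        table3_counts=table3,
        table4_moran=_TABLE4.copy(),
        table6_gini=table6,
    )
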