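"""Domain types and I/O for supply panels, indicator schemas and spatial weights.

The pipeline's raw input is a balanced county x year panel, wide in the
indicators of a multi-dimension service-supply evaluation system, plus a
binary spatial adjacency structure (GAL file or edge list) over the counties.
Everything downstream (index construction, distribution dynamics, Markov
mobility, inequality decomposition) consumes the validated containers
defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorSpec",
    "IndicatorSchema",
    "PanelTable",
    "RegionPartition",
    "SpatialWeights",
    "PanelValidationError",
    "WeightsError",
    "read_panel",
    "write_panel",
    "read_weights",
    "row_standardize",
    "table1_schema",
]

DIMENSIONS = (
    "social_security",
    "care_service",
    "health_support",
    "emotional_comfort",
)

ID_COLUMNS = ("unit_id", "region_id", "year")


class PanelValidationError(ValueError):
    """Raised when a panel file or frame violates the panel contract."""


class WeightsError(ValueError):
    """Raised for malformed spatial weights (self loops, asymmetry, isolates)."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One secondary indicator of the evaluation system.

    ``direction`` is +1 when more is better, -1 for cost-type indicators
    (e.g. premature chronic-disease mortality).  ``fixed_weight`` carries an
    externally supplied weight; entropy weighting ignores it.
    """

    id: str
    label: str
    dimension: str
    direction: int = 1
    unit_label: str = ""
    fixed_weight: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.fixed_weight is not None and not (0.0 <= self.fixed_weight <= 1.0):
            raise ValueError(f"fixed_weight must lie in [0, 1], got {self.fixed_weight}")


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered collection of indicator specs; order fixes matrix column order."""

    indicators: tuple[IndicatorSpec, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.indicators]
        if len(set(ids)) != len(ids):
            raise ValueError("indicator ids must be unique")
        weights = [s.fixed_weight for s in self.indicators]
        if all(w is not None for w in weights) and weights:
            total = float(sum(weights))  # type: ignore[arg-type]
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"fixed weights must sum to 1 within 1e-3, got {total}")

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.indicators]

    @property
    def directions(self) -> np.ndarray:
        return np.array([s.direction for s in self.indicators], dtype=int)

    @property
    def fixed_weights(self) -> np.ndarray:
        if any(s.fixed_weight is None for s in self.indicators):
            raise ValueError("schema has indicators without fixed weights")
        return np.array([s.fixed_weight for s in self.indicators], dtype=float)


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of every unit to exactly one of k ordered regions."""

    assignment: dict[str, str]
    region_order: tuple[str, ...] = ("north", "southwest", "southeast")

    def __post_init__(self) -> None:
        present = set(self.assignment.values())
        missing = [r for r in self.region_order if r not in present]
        if missing:
            raise ValueError(f"empty region(s): {missing}")
        unknown = present - set(self.region_order)
        if unknown:
            raise ValueError(f"units assigned to undeclared region(s): {sorted(unknown)}")

    @property
    def k(self) -> int:
        return len(self.region_order)

    def units_in(self, region: str) -> list[str]:
        return [u for u, r in self.assignment.items() if r == region]


@dataclass
class PanelTable:
    """Balanced unit x year panel, wide in the schema's indicators.

    Invariants enforced by :func:`validate_panel`: every unit observed in
    every year, years consecutive, one region per unit, no missing values.
    """

    data: pd.DataFrame
    schema: IndicatorSchema

    @property
    def units(self) -> list[str]:
        return list(pd.unique(self.data["unit_id"]))

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def partition(self, region_order: tuple[str, ...] | None = None) -> RegionPartition:
        mapping = (
            self.data.drop_duplicates("unit_id").set_index("unit_id")["region_id"].to_dict()
        )
        order = region_order or tuple(pd.unique(self.data["region_id"]))
        return RegionPartition(assignment=mapping, region_order=tuple(order))

    def values_matrix(self) -> np.ndarray:
        """m x n matrix of raw indicator values, rows in data order."""
        return self.data[self.schema.ids].to_numpy(dtype=float)


@dataclass
class SpatialWeights:
    """n x n nonnegative spatial weight matrix over an ordered unit list."""

    units: list[str]
    matrix: np.ndarray
    row_standardized: bool = False
    binary_adjacency: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        if w.shape != (len(self.units), len(self.units)):
            raise WeightsError("weight matrix shape does not match unit list")
        if np.any(np.diag(w) != 0):
            raise WeightsError("self-loop: nonzero diagonal in weight matrix")
        if np.any(w < 0):
            raise WeightsError("negative spatial weight")
        if self.binary_adjacency and not np.array_equal(w, w.T):
            raise WeightsError("binary adjacency must be symmetric")
        self.matrix = w

    @property
    def n(self) -> int:
        return len(self.units)

    def neighbor_counts(self) -> np.ndarray:
        return (self.matrix > 0).sum(axis=1)

    def isolated_units(self) -> list[str]:
        deg = self.neighbor_counts()
        return [u for u, d in zip(self.units, deg) if d == 0]

    def reorder(self, units: list[str]) -> "SpatialWeights":
        """Return the same weights with rows/columns in a new unit order."""
        if set(units) != set(self.units):
            raise WeightsError("unit sets differ; cannot reorder")
        idx = [self.units.index(u) for u in units]
        return replace(self, units=list(units), matrix=self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Panel I/O


def validate_panel(df: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    required = list(ID_COLUMNS) + schema.ids
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"missing column(s): {missing}")

    df = df[required].copy()
    try:
        df["year"] = df["year"].astype(int)
        for c in schema.ids:
            df[c] = pd.to_numeric(df[c], errors="raise")
    except (ValueError, TypeError) as exc:
        raise PanelValidationError(f"non-numeric cell: {exc}") from exc

    if df[schema.ids].isna().any().any():
        bad = df[schema.ids].isna().any()
        raise PanelValidationError(
            f"missing values in indicator(s): {list(bad[bad].index)}"
        )

    dupes = df.duplicated(subset=["unit_id", "year"])
    if dupes.any():
        pair = df.loc[dupes, ["unit_id", "year"]].iloc[0]
        raise PanelValidationError(
            f"duplicate (unit, year) record: ({pair['unit_id']}, {pair['year']})"
        )

    years = sorted(df["year"].unique())
    if years != list(range(years[0], years[-1] + 1)):
        raise PanelValidationError(f"years are not consecutive: {years}")

    counts = df.groupby("unit_id")["year"].count()
    if counts.nunique() != 1 or counts.iloc[0] != len(years):
        short = counts[counts != len(years)]
        raise PanelValidationError(
            f"non-rectangular panel; unit(s) with missing years: {list(short.index)}"
        )

    regions = df.groupby("unit_id")["region_id"].nunique()
    if (regions > 1).any():
        raise PanelValidationError(
            f"unit(s) mapped to multiple regions: {list(regions[regions > 1].index)}"
        )

    return df.sort_values(["unit_id", "year"], kind="stable").reset_index(drop=True)


def read_panel(path, schema: IndicatorSchema, sep: str = ",") -> PanelTable:
    """Read and validate a delimited long-by-unit-year panel file."""
    df = pd.read_csv(path, sep=sep)
    return PanelTable(data=validate_panel(df, schema), schema=schema)


def write_panel(panel: PanelTable, path, sep: str = ",") -> None:
    panel.data.to_csv(path, sep=sep, index=False)


def panel_from_frame(df: pd.DataFrame, schema: IndicatorSchema) -> PanelTable:
    return PanelTable(data=validate_panel(df, schema), schema=schema)


# ---------------------------------------------------------------------------
# Spatial weights I/O


def _edges_to_matrix(edges: list[tuple[str, str]], units: list[str]) -> np.ndarray:
    index = {u: i for i, u in enumerate(units)}
    w = np.zeros((len(units), len(units)))
    for a, b in edges:
        if a == b:
            raise WeightsError(f"self-loop edge ({a}, {a})")
        for u in (a, b):
            if u not in index:
                raise WeightsError(f"unknown unit id in weights file: {u!r}")
        w[index[a], index[b]] = 1.0
    if not np.array_equal(w, w.T):
        i, j = np.argwhere(w != w.T)[0]
        raise WeightsError(f"asymmetric edge set near ({units[i]}, {units[j]})")
    return w


def read_weights(path, units: list[str], warn_isolated: bool = True) -> SpatialWeights:
    """Read binary adjacency from a GAL file or a 2-column edge list.

    GAL: header line with the unit count (optionally preceded by 0 and
    followed by shapefile metadata), then alternating "unit degree" /
    neighbor-id lines.  Edge list: delimited rows ``a,b`` (or whitespace
    separated), undirected; each pair may appear once or in both directions.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise WeightsError("empty weights file")

    head = lines[0].split()
    is_gal = all(tok.lstrip("-").isdigit() for tok in head[:1]) and len(head) <= 4
    edges: list[tuple[str, str]] = []
    if is_gal and len(lines) > 1 and len(lines[1].split()) == 2:
        body = lines[1:]
        i = 0
        while i < len(body):
            unit, deg = body[i].split()
            deg = int(deg)
            neighbors = body[i + 1].split() if deg > 0 else []
            if len(neighbors) != deg:
                raise WeightsError(f"GAL degree mismatch for unit {unit!r}")
            edges.extend((unit, nb) for nb in neighbors)
            i += 2
    else:
        for ln in lines:
            parts = ln.replace(",", " ").split()
            if parts[0].lower() in ("unit_a", "from", "source"):
                continue
            if len(parts) < 2:
                raise WeightsError(f"malformed edge line: {ln!r}")
            a, b = parts[0], parts[1]
            edges.append((a, b))
            edges.append((b, a))

    w = _edges_to_matrix(sorted(set(edges)), units)
    sw = SpatialWeights(units=list(units), matrix=w)
    if warn_isolated and sw.isolated_units():
        warnings.warn(
            f"isolated unit(s) with no neighbors: {sw.isolated_units()}",
            stacklevel=2,
        )
    return sw


def write_gal(weights: SpatialWeights, path) -> None:
    lines = [str(weights.n)]
    for i, u in enumerate(weights.units):
        nbs = [weights.units[j] for j in np.flatnonzero(weights.matrix[i] > 0)]
        lines.append(f"{u} {len(nbs)}")
        lines.append(" ".join(nbs))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def row_standardize(weights: SpatialWeights, allow_isolated: bool = False) -> SpatialWeights:
    """Rescale each row to sum to 1 (isolated rows are an error by default)."""
    sums = weights.matrix.sum(axis=1)
    if np.any(sums == 0):
        isolated = [u for u, s in zip(weights.units, sums) if s == 0]
        if not allow_isolated:
            raise WeightsError(
                f"cannot row-standardize: isolated unit(s) {isolated}; "
                "pass allow_isolated=True to keep zero rows"
            )
        warnings.warn(f"keeping zero rows for isolated unit(s) {isolated}", stacklevel=2)
        sums = np.where(sums == 0, 1.0, sums)
    return SpatialWeights(
        units=list(weights.units),
        matrix=weights.matrix / sums[:, None],
        row_standardized=True,
        binary_adjacency=False,
    )


# ---------------------------------------------------------------------------
# Packaged 21-indicator evaluation schema

_TABLE1_ROWS: list[tuple[str, str, str, float, int, str]] = [
    # (id, label, dimension, weight, direction, unit)
    ("pension_standard", "Basic pension standard", "social_security", 0.052, 1, "10,000 CNY"),
    ("medical_insurance_rate", "Registration rate of basic medical insurance coverage", "social_security", 0.033, 1, "%"),
    ("medical_assistance_exp", "Expenditure on direct medical assistance during the year", "social_security", 0.028, 1, "10,000 CNY"),
    ("legal_aid_centers", "Number of legal aid centers per 1,000 older adults", "social_security", 0.015, 1, "each"),
    ("subsidy_recipients", "Proportion of older adults receiving older adult subsidies", "social_security", 0.038, 1, "person"),
    ("nursing_institutions", "Number of nursing institutions per 1,000 older adults", "care_service", 0.042, 1, "each"),
    ("nursing_bed_share", "Proportion of nursing beds in older adult care institutions", "care_service", 0.068, 1, "%"),
    ("welfare_institutions", "Number of public welfare older adult care institutions per 1,000 older adults", "care_service", 0.049, 1, "each"),
    ("community_facility_value", "Total value of community older adult care (mutual aid) facilities", "care_service", 0.051, 1, "10,000 CNY"),
    ("life_expectancy", "Life expectancy per capita", "care_service", 0.047, 1, "year"),
    ("institution_staff", "Average number of employees in older adult care institutions at year end", "care_service", 0.073, 1, "person"),
    ("medical_beds", "Number of medical beds in health institutions per 1,000 older adults", "health_support", 0.088, 1, "each"),
    ("certified_caregivers", "Number of certified caregivers per 1,000 older adults", "health_support", 0.092, 1, "each"),
    ("rehab_professionals", "Proportion of rehabilitation professionals in the community", "health_support", 0.098, 1, "%"),
    ("chronic_premature_mortality", "Premature mortality rate of major chronic diseases in older adults", "health_support", 0.036, -1, "%"),
    ("health_management_rate", "Health management rate of the older adult population", "health_support", 0.059, 1, "%"),
    ("senior_colleges", "Number of senior colleges per 1,000 older adults", "emotional_comfort", 0.026, 1, "each"),
    ("community_park_area", "Total area of community parks per 1,000 older adults", "emotional_comfort", 0.038, 1, "km^2"),
    ("senior_associations", "Number of older adult association organizations per 1,000 older adults", "emotional_comfort", 0.035, 1, "each"),
    ("activity_stations", "Number of older adult activity stations (centers or activity rooms) per 1,000 older adults", "emotional_comfort", 0.032, 1, "each"),
]


def table1_schema() -> IndicatorSchema:
    """The packaged older-adult-service evaluation schema with published weights.

    Four dimensions (social security, care service, health support,
    emotional comfort); exactly one cost-type indicator (premature mortality
    of major chronic diseases).  Fixed weights sum to 1.000.
    """
    specs = tuple(
        IndicatorSpec(
            id=iid,
            label=label,
            dimension=dim,
            direction=direction,
            unit_label=unit,
            fixed_weight=weight,
        )
        for iid, label, dim, weight, direction, unit in _TABLE1_ROWS
    )
    return IndicatorSchema(indicators=specs)
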