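"""End-to-end orchestration and the summary arithmetic of the report tables.

``run_pipeline`` executes index -> distribution dynamics -> Markov
(+ spatial conditioning and Moran inference when weights are supplied) ->
Dagum Gini -> panel determinants in order, writes every stage's output as a
delimited table with a stable schema, and records a manifest sufficient to
reproduce the run.  Persisted values are full precision; rounding is a
display concern only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .composite_index import build_index_panel
from .core_data import PanelTable, RegionPartition, SpatialWeights
from .determinants import bp_lm_test, fit_fe, fit_pooled, fit_re, hausman_test
from .distribution_dynamics import DEFAULT_BANDWIDTH, curves_frame, kde_series
from .inequality import dagum_by_year
from .mobility import (
    classify_levels,
    count_transitions,
    mle_transition_matrix,
    morans_i_by_year,
    spatial_lag,
    spatial_markov,
)

__all__ = ["PipelineReport", "pct_decline", "period_mean", "run_pipeline"]

logger = logging.getLogger("supplyscape")


def pct_decline(start: float, end: float, decimals: int | None = 2) -> float:
    """Percent decline 100 * (start - end) / start, rounded for display."""
    if start <= 0:
        raise ValueError(f"start value must be positive, got {start}")
    value = 100.0 * (start - end) / start
    return round(value, decimals) if decimals is not None else value


def period_mean(series: pd.Series, years=None, decimals: int | None = 4) -> float:
    """Arithmetic mean of a year-indexed series over a year subset."""
    missing = [] if years is None else [y for y in years if y not in series.index]
    if missing:
        raise ValueError(f"year(s) not in series: {missing}")
    s = series if years is None else series.loc[list(years)]
    if len(s) == 0:
        raise ValueError("empty year selection")
    value = float(s.mean())
    return round(value, decimals) if decimals is not None else value


@dataclass
class PipelineReport:
    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _write(report: PipelineReport, name: str, frame: pd.DataFrame) -> None:
    path = report.out_dir / f"{name}.csv"
    frame.to_csv(path, index=False)
    report.outputs[name] = path


def run_pipeline(
    panel: PanelTable,
    weights: SpatialWeights | None,
    partition: RegionPartition,
    out_dir,
    weight_mode: str = "entropy",
    bandwidth: float = DEFAULT_BANDWIDTH,
    kde_years=None,
    covariate_panel: pd.DataFrame | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run every analysis stage on a validated panel and export the tables.

    ``covariate_panel`` (unit_id, year, five log covariates) enables the
    determinants stage; omitting ``weights`` skips the spatial stages with
    an explicit notice in the report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out_dir)
    started = time.time()

    def stage(name):
        logger.info("stage %s at %.2fs", name, time.time() - started)

    try:
        stage("index")
        index_panel, weight_vec = build_index_panel(panel, weight_mode=weight_mode)
        _write(report, "index", index_panel)
        _write(
            report,
            "weights",
            weight_vec.as_series().rename_axis("indicator_id").reset_index().assign(
                source=weight_vec.source
            ),
        )

        stage("kde")
        years = kde_years or [y for y in (2010, 2012, 2014, 2016, 2018, 2019) if y in panel.years]
        if not years:
            years = panel.years
        curves, features = kde_series(index_panel, partition, years=years, h=bandwidth)
        _write(report, "kde_curves", curves_frame(curves))
        _write(report, "kde_features", features)

        stage("markov")
        levels, scheme = classify_levels(index_panel)
        counts = count_transitions(levels)
        matrix = mle_transition_matrix(counts)
        _write(report, "transition_matrix", matrix.frame().reset_index())

        if weights is not None:
            stage("moran")
            _write(report, "moran", morans_i_by_year(index_panel, weights, rng=seed))
            stage("spatial_markov")
            lags = spatial_lag(index_panel, weights, scheme)
            _write(report, "spatial_transitions", spatial_markov(levels, lags).frame())
        else:
            report.skipped.extend(["moran", "spatial_markov"])
            logger.warning("no spatial weights supplied; Moran and spatial Markov skipped")

        stage("gini")
        dagum = dagum_by_year(index_panel, partition)
        _write(report, "dagum", dagum)

        yearly = dagum[dagum["year"] != "Mean"].set_index("year")["overall"].astype(float)
        first, last = yearly.index.min(), yearly.index.max()
        _write(
            report,
            "change_summary",
            pd.DataFrame(
                {
                    "quantity": ["overall_mean", "overall_decline_pct"],
                    "value": [
                        period_mean(yearly),
                        pct_decline(yearly.loc[first], yearly.loc[last]),
                    ],
                }
            ),
        )

        if covariate_panel is not None:
            stage("panel")
            merged = covariate_panel.merge(
                index_panel[["unit_id", "year", "ci"]], on=["unit_id", "year"]
            )
            if (merged["ci"] <= 0).any():
                raise ValueError("nonpositive index values cannot be logged")
            merged["y"] = np.log(merged["ci"])
            pooled = fit_pooled(merged)
            fe = fit_fe(merged, effects="twoway")
            re = fit_re(merged)
            reg = pd.concat([f.summary_frame() for f in (pooled, fe, re)])
            _write(report, "regression", reg.rename_axis("term").reset_index())
            bp = bp_lm_test(pooled, merged)
            hm = hausman_test(fit_fe(merged, effects="unit"), re)
            _write(
                report,
                "spec_tests",
                pd.DataFrame(
                    [
                        {"test": bp.test, "statistic": bp.statistic, "df": bp.df, "p": bp.p,
                         "stars": bp.stars()},
                        {"test": hm.test, "statistic": hm.statistic, "df": hm.df, "p": hm.p,
                         "stars": hm.stars()},
                        {"test": "wald", "statistic": re.extras["wald"],
                         "df": re.extras["wald_df"], "p": re.extras["wald_p"], "stars": ""},
                    ]
                ),
            )
        else:
            report.skipped.append("panel")
    except Exception as exc:  # annotate the failing stage for the caller
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    report.manifest = {
        "version": _version,
        "seed": seed,
        "weight_mode": weight_mode,
        "bandwidth": bandwidth,
        "n_units": int(panel.n_units),
        "years": [int(y) for y in panel.years],
        "region_order": list(partition.region_order),
        "outputs": {k: str(v) for k, v in report.outputs.items()},
        "skipped": report.skipped,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=2)
    return report
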