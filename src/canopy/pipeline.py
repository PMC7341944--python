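"""End-to-end pipeline orchestration and result writing.

Two entry points mirror the two analyses: :func:`run_index_pipeline` builds
the weighted composite index (with bootstrap bands and diagnostics) from a
population table and a richness table; :func:`run_correlates_pipeline`
computes windowed average rates of change, derives cover covariates, and
fits the univariate mixed-model comparisons.  :func:`run_pipeline` drives
both from a YAML config and writes CSV outputs, logging the population
accounting of every filter rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import correlates as corr
from . import diagnostics as diag
from . import index as idx
from . import io, trends
from .types import CanopyError, CompositeIndex, PopulationSeries

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "baseline_year": 1970,
    "final_year": 2014,
    "cap": 1.0,
    "gam_min_obs": 6,
    "bootstrap": 1000,
    "seed": 1,
    "window": "song",
    "cover_lag": 1,
    "buffer_radius_km": 5.0,  # provenance of the covariate extraction
    "delta_aic_threshold": 2.0,
}


@dataclass
class IndexResult:
    composite: CompositeIndex
    trends: pd.DataFrame
    species_rates: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        years = self.composite.years
        return pd.DataFrame(
            {
                "year": years,
                "index": [self.composite.index[y] for y in years],
                "ci_low": [self.composite.ci_low.get(y, np.nan) for y in years],
                "ci_high": [self.composite.ci_high.get(y, np.nan) for y in years],
                "n_species": [
                    self.composite.n_species_per_year.get(y, 0) for y in years
                ],
            }
        )


def run_index_pipeline(
    series_list: list[PopulationSeries],
    richness: pd.DataFrame,
    baseline_year: int = 1970,
    final_year: int = 2014,
    cap: float = 1.0,
    gam_min_obs: int = 6,
    n_boot: int = 1000,
    seed: int | None = None,
) -> IndexResult:
    """Population fits -> species trends -> weights -> chained index (+CI)."""
    rates, excluded = trends.population_rates(
        series_list, cap=cap, gam_min_obs=gam_min_obs
    )
    used = [s for s in series_list if s.population_id in rates]
    trend_frame = idx.species_trends(rates, used)
    subsets = sorted(
        trend_frame[["realm", "taxon_group"]].drop_duplicates().itertuples(index=False)
    )
    weights = idx.compute_weights(richness, [tuple(s) for s in subsets])
    composite = idx.chain_index(
        trend_frame, weights, baseline_year=baseline_year, final_year=final_year
    )
    if n_boot and n_boot > 0:
        composite.ci_low, composite.ci_high = idx.bootstrap_ci(
            trend_frame,
            weights,
            n_boot=n_boot,
            seed=seed,
            baseline_year=baseline_year,
            final_year=final_year,
        )
    counts = {
        "input": len(series_list),
        "used": len(used),
        "excluded_all_zero": len(excluded),
    }
    log.info(
        "index pipeline: %(input)d populations in, %(used)d used, "
        "%(excluded_all_zero)d excluded (all-zero series)",
        counts,
    )
    return IndexResult(
        composite=composite,
        trends=trend_frame,
        species_rates=idx.species_overall_rates(trend_frame),
        counts=counts,
    )


@dataclass
class CorrelatesResult:
    model_table: pd.DataFrame
    responses: pd.DataFrame
    model_frame: pd.DataFrame
    influence: pd.DataFrame | None = None
    counts: dict[str, int] = field(default_factory=dict)


def run_correlates_pipeline(
    series_list: list[PopulationSeries],
    covariates: pd.DataFrame,
    window: str = "song",
    cap: float = 1.0,
    gam_min_obs: int = 6,
    cover_lag: int = 1,
    predictors: list[str] | None = None,
    run_influence: bool = False,
) -> CorrelatesResult:
    """Windowed responses + cover covariates -> univariate mixed models."""
    if window not in corr.WINDOWS:
        raise CanopyError(f"unknown window {window!r}; use one of {list(corr.WINDOWS)}")
    rates, excluded_zero = trends.population_rates(
        series_list, cap=cap, gam_min_obs=gam_min_obs
    )
    meta = {s.population_id: s for s in series_list}

    responses = []
    failed_window = 0
    for pop_id, annual in rates.items():
        response = corr.windowed_response(annual, window, meta[pop_id])
        if response is None:
            failed_window += 1
            continue
        responses.append(response)

    statics = io.covariate_statics(covariates).set_index("population_id")
    rows = []
    zero_cover = 0
    no_cover = 0
    for response in responses:
        pop_id = response.population_id
        row: dict[str, Any] = {
            "population_id": pop_id,
            "avg_rate": response.avg_rate,
            "location_id": response.location_id,
            "genus": response.genus,
            "specialist": response.specialist,
            "window": response.window,
            "first_year": response.study_period[0],
            "last_year": response.study_period[1],
            "exploitation": int(meta[pop_id].exploitation_primary_threat),
        }
        static = statics.loc[pop_id] if pop_id in statics.index else None
        cover, bare, loss = io.covariate_series(covariates, pop_id)
        if cover:
            try:
                fitted = corr.smooth_cover_series(cover, gam_min_obs=gam_min_obs)
                cov = corr.derive_cover_covariates(
                    pop_id,
                    fitted,
                    bare,
                    loss,
                    response.study_period,
                    cover_2000=float(static["cover_2000"]) if static is not None else np.nan,
                    cover_2010=float(static["cover_2010"]) if static is not None else np.nan,
                    lag=cover_lag,
                )
            except CanopyError as exc:
                log.info("cover covariates unavailable: %s", exc)
                zero_cover += 1
                continue
            row.update(
                {
                    "mean_tree_cover": cov.mean_tree_cover,
                    "mean_bare_ground": cov.mean_bare_ground,
                    "cover_trend": cov.cover_trend,
                    "cover_2000": cov.cover_2000,
                    "loss_area": cov.loss_area,
                    "prop_change_2000_2010": cov.prop_change_2000_2010,
                }
            )
        else:
            no_cover += 1
        if static is not None:
            for name in ("body_mass_g", "road_density", "hpd", "travel_time"):
                if name in static.index:
                    row[name] = float(static[name])
        rows.append(row)

    response_frame = pd.DataFrame(rows)
    taxonomy = pd.DataFrame(
        {
            "population_id": [s.population_id for s in series_list],
            "genus": [s.genus for s in series_list],
            "family": [s.family for s in series_list],
            "order": [s.order for s in series_list],
        }
    )
    model_frame = corr.prepare_predictors(
        response_frame, pd.DataFrame(), taxonomy=taxonomy
    )

    tables = [corr.compare_all_predictors(model_frame, predictors, subset_label="all")]
    specialist_frame = model_frame[model_frame["specialist"]]
    if specialist_frame["population_id"].nunique() >= 10:
        # re-standardize over the specialist subset only
        spec_frame = corr.prepare_predictors(
            response_frame[response_frame["specialist"]].reset_index(drop=True),
            pd.DataFrame(),
            taxonomy=taxonomy,
        )
        tables.append(
            corr.compare_all_predictors(spec_frame, predictors, subset_label="specialists")
        )
    model_table = pd.concat(tables, ignore_index=True)

    influence = None
    if run_influence and not model_table.empty:
        influence = corr.genus_influence(
            model_frame, model_table["predictor"].unique().tolist()
        )

    counts = {
        "input": len(series_list),
        "rates_fitted": len(rates),
        "excluded_all_zero": len(excluded_zero),
        "failed_window_rule": failed_window,
        "zero_or_missing_cover": zero_cover,
        "no_cover_series": no_cover,
        "used": int(len(response_frame)),
    }
    log.info(
        "correlates pipeline (%s window): %d in, %d with responses, "
        "%d failed window rule, %d dropped for zero/missing cover",
        window,
        counts["input"],
        counts["used"],
        failed_window,
        zero_cover,
    )
    return CorrelatesResult(
        model_table=model_table,
        responses=response_frame,
        model_frame=model_frame,
        influence=influence,
        counts=counts,
    )


def run_synthetic_index(scenario, seed: int, n_boot: int = 0) -> IndexResult:
    """Generate one scenario draw and run the full index pipeline on it."""
    from .io import population_series_from_frame
    from .simulate import generate_populations, generate_richness

    populations, _ = generate_populations(scenario, seed)
    series = population_series_from_frame(populations)
    return run_index_pipeline(
        series, generate_richness(scenario), n_boot=n_boot, seed=seed
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    config = dict(DEFAULT_CONFIG)
    config.update(user)
    return config


def run_pipeline(config_path: str | Path) -> Path:
    """Run the stages named in a YAML config and write the result bundle.

    Writes ``index.csv``, ``species_trends.csv``, ``diagnostics.csv``,
    ``group_means.csv`` and, when a covariate table is configured,
    ``model_comparison.csv`` into the configured ``out_dir``.
    """
    config = load_config(config_path)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    series_list = io.read_population_table(config["populations"])
    richness = io.read_richness_table(config["richness"])

    result = run_index_pipeline(
        series_list,
        richness,
        baseline_year=config["baseline_year"],
        final_year=config["final_year"],
        cap=config["cap"],
        gam_min_obs=config["gam_min_obs"],
        n_boot=config["bootstrap"],
        seed=config["seed"],
    )
    result.as_frame().to_csv(out_dir / "index.csv", index=False)
    result.species_rates.to_csv(out_dir / "species_trends.csv", index=False)
    diag.percent_declining_by_year(result.trends).to_csv(
        out_dir / "diagnostics.csv", index=False
    )
    summaries = []
    for grouping in diag.GROUPINGS:
        summary = diag.group_mean_rates(result.species_rates, grouping)
        summary.insert(0, "grouping", grouping)
        summaries.append(summary)
    pd.concat(summaries, ignore_index=True).to_csv(
        out_dir / "group_means.csv", index=False
    )

    if config.get("covariates"):
        covariates = io.read_covariate_table(config["covariates"])
        correlates_result = run_correlates_pipeline(
            series_list,
            covariates,
            window=config["window"],
            cap=config["cap"],
            gam_min_obs=config["gam_min_obs"],
            cover_lag=config["cover_lag"],
        )
        correlates_result.model_table.to_csv(
            out_dir / "model_comparison.csv", index=False
        )
    log.info("pipeline outputs written to %s", out_dir)
    return out_dir
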