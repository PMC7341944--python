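"""Composite index construction: species trends, diversity weights, chaining, bootstrap.

Population rates are averaged to species trends within each
(realm, taxonomic-group) subset; subsets are averaged with two-level weights
proportional to forest species richness (realm first, then taxon within
realm); and the weighted mean annual rate dbar_t is chained into an index
``I_t = I_{t-1} * 10**dbar_t`` with ``I_{baseline} = 1``.  Confidence bands
come from resampling species with replacement within each subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    AnnualRates,
    CanopyError,
    CompositeIndex,
    PopulationSeries,
    WeightingScheme,
)

log = logging.getLogger(__name__)

BASELINE_YEAR = 1970
FINAL_YEAR = 2014


def compute_weights(
    richness: pd.DataFrame, available_subsets: list[tuple[str, str]]
) -> WeightingScheme:
    """Diversity weights from a realm x taxon species-richness table.

    Realm weights are proportional to each realm's total forest species count;
    taxon weights within a realm are proportional to that taxon's count,
    renormalised over the taxa actually holding data in that realm.  A subset
    present in the data but absent from the richness table is a fatal error.
    """
    table = richness.set_index(["realm", "taxon_group"])["species_count"]
    missing = [s for s in available_subsets if s not in table.index]
    if missing:
        raise CanopyError(f"subsets missing from richness table: {missing}")

    realms = sorted({realm for realm, _ in available_subsets})
    realm_totals = {
        realm: float(table.loc[realm].sum()) for realm in realms
    }
    total = sum(realm_totals.values())
    realm_weights = {realm: realm_totals[realm] / total for realm in realms}

    taxon_weights: dict[tuple[str, str], float] = {}
    for realm in realms:
        taxa = [taxon for r, taxon in available_subsets if r == realm]
        counts = {taxon: float(table[(realm, taxon)]) for taxon in taxa}
        subtotal = sum(counts.values())
        for taxon in taxa:
            taxon_weights[(realm, taxon)] = counts[taxon] / subtotal

    return WeightingScheme(
        realm_weights=realm_weights,
        taxon_weights=taxon_weights,
        subsets=tuple(sorted(available_subsets)),
    )


def species_trends(
    rates: dict[str, AnnualRates], series_list: list[PopulationSeries]
) -> pd.DataFrame:
    """Average population rates to species-level annual trends.

    Returns a tidy frame with one row per (species, subset, year):
    columns ``species_id, realm, taxon_group, biome_group, year, rate`` where
    ``rate`` is the arithmetic mean of d_t over that species' populations with
    a rate in that year.  A species surveyed in two realms contributes one
    trend per subset, matching the subset-wise aggregation of the index.
    """
    meta = {s.population_id: s for s in series_list}
    records = []
    for pop_id, annual in rates.items():
        series = meta[pop_id]
        for year, d in annual.rates.items():
            records.append(
                (
                    series.species_id,
                    series.realm,
                    series.taxon_group,
                    series.biome_group,
                    year,
                    d,
                )
            )
    frame = pd.DataFrame(
        records,
        columns=["species_id", "realm", "taxon_group", "biome_group", "year", "rate"],
    )
    grouped = (
        frame.groupby(
            ["species_id", "realm", "taxon_group", "biome_group", "year"],
            as_index=False,
        )["rate"]
        .mean()
        .sort_values(["species_id", "year"], ignore_index=True)
    )
    return grouped


def species_overall_rates(trends: pd.DataFrame) -> pd.DataFrame:
    """Overall rate per species-subset: mean of its annual mean rates."""
    return (
        trends.groupby(
            ["species_id", "realm", "taxon_group", "biome_group"], as_index=False
        )["rate"]
        .mean()
        .rename(columns={"rate": "overall_rate"})
    )


def subset_annual_rates(
    trends: pd.DataFrame, subset: tuple[str, str]
) -> pd.Series:
    """Arithmetic mean across species of a subset's annual rates, by year."""
    realm, taxon = subset
    sub = trends[(trends["realm"] == realm) & (trends["taxon_group"] == taxon)]
    return sub.groupby("year")["rate"].mean()


def _weighted_annual_rates(
    subset_rates: dict[tuple[str, str], pd.Series],
    weights: WeightingScheme,
    years: np.ndarray,
) -> np.ndarray:
    """dbar_t with hierarchical yearly renormalisation over data-bearing subsets."""
    dbar = np.zeros(years.size)
    for i, year in enumerate(years):
        per_realm: dict[str, dict[str, float]] = {}
        for (realm, taxon), rates in subset_rates.items():
            if year in rates.index:
                per_realm.setdefault(realm, {})[taxon] = rates.loc[year]
        if not per_realm:
            continue  # index stays flat through an all-empty year
        realm_w = {r: weights.realm_weights[r] for r in per_realm}
        realm_norm = sum(realm_w.values())
        value = 0.0
        for realm, taxa in per_realm.items():
            taxon_w = {g: weights.taxon_weights[(realm, g)] for g in taxa}
            taxon_norm = sum(taxon_w.values())
            realm_rate = sum(
                taxa[g] * taxon_w[g] / taxon_norm for g in taxa
            )
            value += realm_rate * realm_w[realm] / realm_norm
        dbar[i] = value
    return dbar


def chain_index(
    trends: pd.DataFrame,
    weights: WeightingScheme,
    baseline_year: int = BASELINE_YEAR,
    final_year: int = FINAL_YEAR,
) -> CompositeIndex:
    """Chain weighted mean annual rates into the composite index.

    A rate in year t describes the change from t-1 to t, so the chain starts
    at ``baseline_year`` with value 1 and multiplies by ``10**dbar_t`` for
    each following year.  Weights are renormalised each year over the subsets
    that hold data; a year with no data anywhere leaves the index flat.
    """
    in_span = trends[
        (trends["year"] > baseline_year) & (trends["year"] <= final_year)
    ]
    if not (in_span["year"] == baseline_year + 1).any():
        raise CanopyError(
            f"no subset has data in the baseline year {baseline_year}; "
            "choose a later baseline"
        )
    subset_rates = {
        subset: subset_annual_rates(in_span, subset) for subset in weights.subsets
    }
    rate_years = np.arange(baseline_year + 1, final_year + 1)
    dbar = _weighted_annual_rates(subset_rates, weights, rate_years)

    years = [baseline_year, *rate_years.tolist()]
    values = np.concatenate([[1.0], 10.0 ** np.cumsum(dbar)])
    n_species = in_span.groupby("year")["species_id"].nunique()
    return CompositeIndex(
        years=years,
        index={int(y): float(v) for y, v in zip(years, values)},
        n_species_per_year={
            int(y): int(n_species.get(y, 0)) for y in rate_years
        },
    )


def bootstrap_ci(
    trends: pd.DataFrame,
    weights: WeightingScheme,
    n_boot: int = 1000,
    seed: int | None = None,
    baseline_year: int = BASELINE_YEAR,
    final_year: int = FINAL_YEAR,
    ci_level: float = 0.95,
) -> tuple[dict[int, float], dict[int, float]]:
    """Percentile bootstrap bands for the chained index.

    Species (the independent units of the index) are resampled with
    replacement within each subset; the index is re-chained for each of
    ``n_boot`` resamples and per-year percentile bounds are returned.
    A subset with a single species contributes a degenerate (zero-width)
    resample and is warned about.
    """
    rng = np.random.default_rng(seed)
    rate_years = np.arange(baseline_year + 1, final_year + 1)
    in_span = trends[
        (trends["year"] > baseline_year) & (trends["year"] <= final_year)
    ]

    # species x year rate matrix per subset (NaN where the species has no rate)
    matrices: dict[tuple[str, str], np.ndarray] = {}
    for subset in weights.subsets:
        realm, taxon = subset
        sub = in_span[
            (in_span["realm"] == realm) & (in_span["taxon_group"] == taxon)
        ]
        if sub.empty:
            continue
        pivot = sub.pivot_table(
            index="species_id", columns="year", values="rate", aggfunc="mean"
        ).reindex(columns=rate_years)
        if pivot.shape[0] == 1:
            log.warning(
                "subset %s has a single species; its bootstrap band is degenerate",
                subset,
            )
        matrices[subset] = pivot.to_numpy()

    alpha = (1.0 - ci_level) / 2.0
    curves = np.empty((n_boot, rate_years.size + 1))
    for b in range(n_boot):
        subset_rates = {}
        for subset, matrix in matrices.items():
            n_species = matrix.shape[0]
            draw = matrix[rng.integers(0, n_species, n_species)]
            present = np.sum(~np.isnan(draw), axis=0)
            with np.errstate(invalid="ignore"):
                mean = np.where(
                    present > 0, np.nansum(draw, axis=0) / np.maximum(present, 1), np.nan
                )
            series = pd.Series(mean, index=rate_years).dropna()
            subset_rates[subset] = series
        dbar = _weighted_annual_rates(subset_rates, weights, rate_years)
        curves[b] = np.concatenate([[1.0], 10.0 ** np.cumsum(dbar)])

    low = np.quantile(curves, alpha, axis=0)
    high = np.quantile(curves, 1.0 - alpha, axis=0)
    years = [baseline_year, *rate_years.tolist()]
    return (
        {int(y): float(v) for y, v in zip(years, low)},
        {int(y): float(v) for y, v in zip(years, high)},
    )


def implied_annual_change_percent(final_index: float, n_steps: int) -> float:
    """Constant annual percentage decline implied by a final index value.

    An index ending at I after n annual steps corresponds to a constant
    annual multiplicative change of I**(1/n); this returns the decline
    ``100 * (1 - I**(1/n))`` in percent per year.
    """
    return 100.0 * (1.0 - final_index ** (1.0 / n_steps))
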