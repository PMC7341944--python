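"""Reading, validating, and writing the three input tables.

All tables are UTF-8 CSV with a header and '.' decimal separator.
Time-indexed fields are long format (one row per population-year); static
per-population fields in the covariate table are repeated on every row of
that population and validated to be constant.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    PopulationSeries,
    REALMS,
    TAXON_GROUPS,
    ValidationError,
)

log = logging.getLogger(__name__)

POPULATION_COLUMNS = [
    "population_id",
    "species_id",
    "genus",
    "taxon_group",
    "realm",
    "biome_group",
    "specialist",
    "location_id",
    "exploitation_primary_threat",
    "year",
    "abundance",
]
OPTIONAL_POPULATION_COLUMNS = ["family", "order"]

RICHNESS_COLUMNS = ["realm", "taxon_group", "species_count"]

COVARIATE_ANNUAL_COLUMNS = [
    "population_id",
    "year",
    "tree_cover_km2",
    "bare_ground_km2",
    "loss_km2",
]
COVARIATE_STATIC_COLUMNS = [
    "cover_2000",
    "cover_2010",
    "body_mass_g",
    "road_density",
    "hpd",
    "travel_time",
]


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what}: missing required column(s) {missing}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def read_population_table(path: str | Path) -> list[PopulationSeries]:
    """Parse and validate a long-format population abundance table.

    Row-level contract violations (duplicate population-year, negative
    abundance, unknown labels, fewer than two observation years) are fatal
    and name the offending population/year.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, POPULATION_COLUMNS, f"population table {path}")

    dup = frame.duplicated(subset=["population_id", "year"], keep=False)
    if dup.any():
        offenders = frame.loc[dup, ["population_id", "year"]].drop_duplicates()
        raise ValidationError(
            "duplicate (population_id, year) rows: "
            + ", ".join(f"({r.population_id}, {r.year})" for r in offenders.itertuples())
        )
    negative = frame["abundance"] < 0
    if negative.any():
        offenders = frame.loc[negative, ["population_id", "year"]]
        raise ValidationError(
            "negative abundance for: "
            + ", ".join(f"({r.population_id}, {r.year})" for r in offenders.itertuples())
        )
    bad_realm = ~frame["realm"].isin(REALMS)
    if bad_realm.any():
        raise ValidationError(
            f"unknown realm label(s): {sorted(frame.loc[bad_realm, 'realm'].unique())}"
        )
    bad_taxon = ~frame["taxon_group"].isin(TAXON_GROUPS)
    if bad_taxon.any():
        raise ValidationError(
            "unknown taxon_group label(s): "
            f"{sorted(frame.loc[bad_taxon, 'taxon_group'].unique())}"
        )

    series_list = population_series_from_frame(frame)
    log.info("read %d populations from %s", len(series_list), path)
    return series_list


def population_series_from_frame(frame: pd.DataFrame) -> list[PopulationSeries]:
    """Build validated :class:`PopulationSeries` records from a long frame."""
    frame = frame.sort_values(["population_id", "year"])
    frame = frame.assign(
        specialist=_as_bool(frame["specialist"]),
        exploitation_primary_threat=_as_bool(frame["exploitation_primary_threat"]),
    )
    series_list = []
    for pop_id, sub in frame.groupby("population_id", sort=True):
        tags = sub.iloc[0]
        if len(sub) < 2:
            raise ValidationError(
                f"{pop_id}: needs >=2 observation years, got {len(sub)}"
            )
        series_list.append(
            PopulationSeries(
                population_id=str(pop_id),
                species_id=str(tags["species_id"]),
                genus=str(tags["genus"]),
                taxon_group=str(tags["taxon_group"]),
                realm=str(tags["realm"]),
                biome_group=str(tags["biome_group"]),
                specialist=bool(tags["specialist"]),
                location_id=str(tags["location_id"]),
                exploitation_primary_threat=bool(
                    tags["exploitation_primary_threat"]
                ),
                observations={
                    int(r.year): float(r.abundance) for r in sub.itertuples()
                },
                family=str(tags["family"]) if "family" in sub.columns else None,
                order=str(tags["order"]) if "order" in sub.columns else None,
            )
        )
    return series_list


def write_population_table(series_list: list[PopulationSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for year, abundance in s.observations.items():
            rows.append(
                {
                    "population_id": s.population_id,
                    "species_id": s.species_id,
                    "genus": s.genus,
                    "family": s.family,
                    "order": s.order,
                    "taxon_group": s.taxon_group,
                    "realm": s.realm,
                    "biome_group": s.biome_group,
                    "specialist": s.specialist,
                    "location_id": s.location_id,
                    "exploitation_primary_threat": s.exploitation_primary_threat,
                    "year": year,
                    "abundance": abundance,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_richness_table(path: str | Path) -> pd.DataFrame:
    """Parse a realm,taxon_group,species_count richness table."""
    frame = pd.read_csv(path)
    _require_columns(frame, RICHNESS_COLUMNS, f"richness table {path}")
    bad_realm = ~frame["realm"].isin(REALMS)
    if bad_realm.any():
        raise ValidationError(
            f"unknown realm label(s): {sorted(frame.loc[bad_realm, 'realm'].unique())}"
        )
    bad_taxon = ~frame["taxon_group"].isin(TAXON_GROUPS)
    if bad_taxon.any():
        raise ValidationError(
            "unknown taxon_group label(s): "
            f"{sorted(frame.loc[bad_taxon, 'taxon_group'].unique())}"
        )
    nonpositive = frame["species_count"] <= 0
    if nonpositive.any():
        offenders = frame.loc[nonpositive, ["realm", "taxon_group"]]
        raise ValidationError(
            "species_count must be > 0 for: "
            + ", ".join(f"({r.realm}, {r.taxon_group})" for r in offenders.itertuples())
        )
    if frame.duplicated(subset=["realm", "taxon_group"]).any():
        raise ValidationError("duplicate (realm, taxon_group) rows in richness table")
    return frame[RICHNESS_COLUMNS].reset_index(drop=True)


def write_richness_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame[RICHNESS_COLUMNS].to_csv(path, index=False)


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    """Parse the long-format covariate table (annual + repeated static fields).

    Any field may be missing (empty cells become NaN); static fields must be
    constant within each population.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, COVARIATE_ANNUAL_COLUMNS, f"covariate table {path}")
    for column in ("tree_cover_km2", "bare_ground_km2", "loss_km2"):
        negative = frame[column] < 0
        if negative.any():
            offenders = frame.loc[negative, "population_id"].unique()
            raise ValidationError(
                f"{column} must be >= 0; offending populations: {sorted(offenders)}"
            )
    static_present = [c for c in COVARIATE_STATIC_COLUMNS if c in frame.columns]
    varying = [
        c
        for c in static_present
        if (frame.groupby("population_id")[c].nunique(dropna=True) > 1).any()
    ]
    if varying:
        raise ValidationError(
            f"static covariate(s) vary within a population: {varying}"
        )
    return frame


def write_covariate_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def covariate_statics(frame: pd.DataFrame) -> pd.DataFrame:
    """One row per population of the static covariate fields."""
    static_present = [c for c in COVARIATE_STATIC_COLUMNS if c in frame.columns]
    return (
        frame[["population_id", *static_present]]
        .drop_duplicates("population_id")
        .reset_index(drop=True)
    )


def covariate_series(
    frame: pd.DataFrame, population_id: str
) -> tuple[dict[int, float], dict[int, float], dict[int, float]]:
    """(tree cover, bare ground, loss) annual maps for one population."""
    sub = frame[frame["population_id"] == population_id].sort_values("year")
    years = sub["year"].astype(int).to_numpy()
    def _series(column: str) -> dict[int, float]:
        return {
            int(y): float(v)
            for y, v in zip(years, sub[column].to_numpy())
            if not np.isnan(v)
        }
    return (
        _series("tree_cover_km2"),
        _series("bare_ground_km2"),
        _series("loss_km2"),
    )
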