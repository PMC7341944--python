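"""Synthetic LPD-style data with known ground truth.

Real inputs to this pipeline — a Living-Planet-style population table,
richness-based weights, and satellite-derived buffer covariates — are either
confidential or require remote extraction.  This module generates tables
with the same shape and invariants and a known data-generating process, so
every pipeline stage has a download-free recovery test: population abundance
series follow exponential trends with multiplicative lognormal observation
noise and yearly dropout, and buffer tree-cover series follow linear trends
with AR(1) noise.  Ground-truth sidecar tables (true rate per population,
true cover slope per location) are part of the output contract.

The default :class:`Scenario` mirrors the forest-specialist study layout:
455 populations of 268 species across the 14 populated realm-by-taxon
subsets (no Palaearctic herptiles), spans inside 1970-2014.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .types import BUFFER_AREA_KM2, REALMS, TAXON_GROUPS

# realm -> biome group used for labelling
_BIOME = {
    "Nearctic": "temperate",
    "Palaearctic": "temperate",
    "Neotropical": "tropical",
    "Afrotropical": "tropical",
    "IndoPacific": "tropical",
}

# species per (realm, taxon): 135 birds, 89 mammals, 44 herptiles = 268 species
_DEFAULT_SPECIES = {
    ("Nearctic", "birds"): 27,
    ("Palaearctic", "birds"): 27,
    ("Neotropical", "birds"): 27,
    ("Afrotropical", "birds"): 27,
    ("IndoPacific", "birds"): 27,
    ("Nearctic", "mammals"): 18,
    ("Palaearctic", "mammals"): 18,
    ("Neotropical", "mammals"): 18,
    ("Afrotropical", "mammals"): 18,
    ("IndoPacific", "mammals"): 17,
    ("Nearctic", "herptiles"): 11,
    ("Neotropical", "herptiles"): 11,
    ("Afrotropical", "herptiles"): 11,
    ("IndoPacific", "herptiles"): 11,
}

# plausible forest species richness per subset, for the weighting table
_DEFAULT_RICHNESS = {
    ("Nearctic", "birds"): 250,
    ("Palaearctic", "birds"): 400,
    ("Neotropical", "birds"): 1900,
    ("Afrotropical", "birds"): 1000,
    ("IndoPacific", "birds"): 1600,
    ("Nearctic", "mammals"): 120,
    ("Palaearctic", "mammals"): 180,
    ("Neotropical", "mammals"): 700,
    ("Afrotropical", "mammals"): 550,
    ("IndoPacific", "mammals"): 650,
    ("Nearctic", "herptiles"): 150,
    ("Palaearctic", "herptiles"): 120,
    ("Neotropical", "herptiles"): 1800,
    ("Afrotropical", "herptiles"): 700,
    ("IndoPacific", "herptiles"): 900,
}


@dataclass
class Scenario:
    """Parameters of the synthetic data-generating process."""

    species_per_subset: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_SPECIES)
    )
    richness: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_RICHNESS)
    )
    n_populations: int = 455
    first_year: int = 1970
    last_year: int = 2014
    first_year_latest: int = 2000  # latest allowed series start
    min_span: int = 8  # minimum last-first of a series
    missingness: float = 0.2  # per interior year (endpoints always kept)
    mu_log10_rate: float = math.log10(0.983)  # true annual log10 change
    sigma_rate: float = 0.0  # between-population SD of the true rate
    sigma_obs: float = 0.05  # lognormal observation noise (natural-log SD)
    exploitation_prob: float = 0.0
    exploitation_delta: float = 0.0  # shift of true log10 rate when exploited
    populations_per_location: float = 1.8
    # tree-cover model (per location): cover_t = clip(a + b*t + AR1, 0, area)
    cover_years: tuple[int, int] = (1982, 2016)
    cover_intercept_range: tuple[float, float] = (20.0, 75.0)
    cover_slope_mean: float = -0.2  # km^2 / yr
    cover_slope_sd: float = 0.15
    cover_ar_phi: float = 0.6
    cover_ar_sigma: float = 2.0
    buffer_area: float = BUFFER_AREA_KM2

    @classmethod
    def forest_specialists(cls) -> "Scenario":
        """Headline layout: all populations decline 1.7%/yr (factor 0.983)."""
        return cls()

    @classmethod
    def terrestrial(cls) -> "Scenario":
        """Terrestrial-style layout: annual change factor 0.988 (1.2%/yr)."""
        return cls(mu_log10_rate=math.log10(0.988))


class SyntheticData(NamedTuple):
    populations: pd.DataFrame
    richness: pd.DataFrame
    covariates: pd.DataFrame
    population_truth: pd.DataFrame
    cover_truth: pd.DataFrame


def generate_richness(scenario: Scenario) -> pd.DataFrame:
    """Richness table covering exactly the subsets that hold species."""
    rows = [
        {"realm": realm, "taxon_group": taxon, "species_count": count}
        for (realm, taxon), count in sorted(scenario.richness.items())
        if scenario.species_per_subset.get((realm, taxon), 0) > 0
    ]
    return pd.DataFrame(rows)


def _assign_species(scenario: Scenario, rng: np.random.Generator):
    species = []
    i = 0
    for (realm, taxon), count in sorted(scenario.species_per_subset.items()):
        for _ in range(count):
            species.append(
                {
                    "species_id": f"S{i:04d}",
                    "genus": f"G{i // 3:03d}",
                    "family": f"F{i // 9:03d}",
                    "order": f"O{i // 27:02d}",
                    "realm": realm,
                    "taxon_group": taxon,
                    "biome_group": _BIOME[realm],
                }
            )
            i += 1
    n_extra = scenario.n_populations - len(species)
    if n_extra < 0:
        raise ValueError("n_populations must be >= total species count")
    extra = rng.integers(0, len(species), n_extra)
    counts = np.ones(len(species), dtype=int)
    for j in extra:
        counts[j] += 1
    return species, counts


def generate_populations(
    scenario: Scenario, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format population table plus its ground-truth sidecar.

    Abundance follows ``N_t = N_first * 10**(r*(t - first)) * exp(eps_t)``
    with ``eps_t ~ N(0, sigma_obs^2)``; interior years drop out independently
    with the configured missingness while the first and last years are always
    observed, so every series keeps at least two usable years.
    """
    rng = np.random.default_rng(seed)
    species, pop_counts = _assign_species(scenario, rng)
    n_locations = max(1, int(round(scenario.n_populations / scenario.populations_per_location)))

    rows = []
    truth = []
    pop_i = 0
    for sp, n_pops in zip(species, pop_counts):
        for _ in range(n_pops):
            pop_id = f"P{pop_i:04d}"
            pop_i += 1
            first = int(rng.integers(scenario.first_year, scenario.first_year_latest + 1))
            last = int(rng.integers(first + scenario.min_span, scenario.last_year + 1))
            rate = rng.normal(scenario.mu_log10_rate, scenario.sigma_rate)
            exploited = bool(rng.random() < scenario.exploitation_prob)
            if exploited:
                rate += scenario.exploitation_delta
            location = f"L{rng.integers(0, n_locations):04d}"
            n0 = 10.0 ** rng.uniform(1.0, 4.0)
            years = np.arange(first, last + 1)
            keep = rng.random(years.size) >= scenario.missingness
            keep[0] = keep[-1] = True
            years = years[keep]
            log_true = np.log10(n0) + rate * (years - first)
            abundance = 10.0**log_true * np.exp(
                rng.normal(0.0, scenario.sigma_obs, years.size)
            )
            for year, value in zip(years, abundance):
                rows.append(
                    {
                        "population_id": pop_id,
                        "species_id": sp["species_id"],
                        "genus": sp["genus"],
                        "family": sp["family"],
                        "order": sp["order"],
                        "taxon_group": sp["taxon_group"],
                        "realm": sp["realm"],
                        "biome_group": sp["biome_group"],
                        "specialist": True,
                        "location_id": location,
                        "exploitation_primary_threat": exploited,
                        "year": int(year),
                        "abundance": float(value),
                    }
                )
            truth.append(
                {
                    "population_id": pop_id,
                    "true_log10_rate": float(rate),
                    "exploited": exploited,
                    "first_year": first,
                    "last_year": last,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def generate_covariates(
    scenario: Scenario, populations: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual cover/loss series per population plus static pressures.

    Cover is generated once per location (populations at the same location
    share a buffer) as a linear trend plus AR(1) noise, clipped to the
    physical range; annual loss is the year-on-year cover decrease (never
    negative).  Static covariates are drawn from broad, realistic ranges.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = scenario.cover_years
    years = np.arange(y0, y1 + 1)

    loc_frames: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for location in sorted(populations["location_id"].unique()):
        intercept = rng.uniform(*scenario.cover_intercept_range)
        slope = rng.normal(scenario.cover_slope_mean, scenario.cover_slope_sd)
        noise = np.zeros(years.size)
        eps = rng.normal(0.0, scenario.cover_ar_sigma, years.size)
        for i in range(years.size):
            noise[i] = (
                scenario.cover_ar_phi * noise[i - 1] + eps[i] if i else eps[i]
            )
        cover = np.clip(intercept + slope * (years - y0) + noise, 0.0, scenario.buffer_area)
        bare = np.clip(
            scenario.buffer_area - cover - rng.uniform(0, 10, years.size),
            0.0,
            scenario.buffer_area,
        )
        loss = np.maximum(0.0, -np.diff(cover, prepend=cover[0]))
        loc_frames[location] = pd.DataFrame(
            {
                "year": years,
                "tree_cover_km2": cover,
                "bare_ground_km2": bare,
                "loss_km2": loss,
            }
        )
        truth_rows.append(
            {"location_id": location, "true_cover_slope": float(slope)}
        )

    statics = (
        populations[["population_id", "species_id", "location_id"]]
        .drop_duplicates("population_id")
        .reset_index(drop=True)
    )
    species_mass = {
        sp: 10.0 ** rng.normal(2.5, 1.0)
        for sp in sorted(populations["species_id"].unique())
    }
    frames = []
    for _, row in statics.iterrows():
        annual = loc_frames[row["location_id"]].copy()
        annual.insert(0, "population_id", row["population_id"])
        cov2000 = float(
            annual.loc[annual["year"] == 2000, "tree_cover_km2"].iloc[0]
        )
        cov2010 = float(
            annual.loc[annual["year"] == 2010, "tree_cover_km2"].iloc[0]
        )
        annual["cover_2000"] = cov2000
        annual["cover_2010"] = cov2010
        annual["body_mass_g"] = species_mass[row["species_id"]]
        annual["road_density"] = rng.exponential(5.0)
        annual["hpd"] = 10.0 ** rng.normal(1.5, 0.8)
        annual["travel_time"] = 10.0 ** rng.normal(2.0, 0.5)
        frames.append(annual)
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


def generate_all(scenario: Scenario, seed: int) -> SyntheticData:
    """Generate the three input tables and both ground-truth sidecars."""
    populations, pop_truth = generate_populations(scenario, seed)
    covariates, cover_truth = generate_covariates(scenario, populations, seed + 1)
    return SyntheticData(
        populations=populations,
        richness=generate_richness(scenario),
        covariates=covariates,
        population_truth=pop_truth,
        cover_truth=cover_truth,
    )


def simulate_response_frame(
    n_populations: int = 500,
    n_locations: int = 100,
    n_genera: int = 25,
    exploitation_prob: float = 0.2,
    exploitation_delta: float = -0.02,
    baseline_rate: float = -0.005,
    location_sd: float = 0.02,
    residual_sd: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Population-level response frame for mixed-model power/size studies.

    Generates average rates of change directly at the response level:
    ``avg_rate = baseline + delta*exploited + u_location + eps`` — the model
    the correlates stage assumes, with a known effect size.
    """
    rng = np.random.default_rng(seed)
    location = rng.integers(0, n_locations, n_populations)
    genus = rng.integers(0, n_genera, n_populations)
    exploited = (rng.random(n_populations) < exploitation_prob).astype(int)
    u = rng.normal(0.0, location_sd, n_locations)
    avg_rate = (
        baseline_rate
        + exploitation_delta * exploited
        + u[location]
        + rng.normal(0.0, residual_sd, n_populations)
    )
    return pd.DataFrame(
        {
            "population_id": [f"P{i:04d}" for i in range(n_populations)],
            "avg_rate": avg_rate,
            "exploitation": exploited,
            "location_id": [f"L{i:03d}" for i in location],
            "genus": [f"G{i:03d}" for i in genus],
        }
    )


def simulate_influence_frame(
    n_genera: int = 20,
    populations_per_genus: int = 15,
    effect: float = 0.02,
    genus_sd: float = 0.005,
    residual_sd: float = 0.05,
    influential_genus: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Frame for the leave-one-genus-out influence analysis.

    The bulk of the data carries a genuine predictor effect.  With
    ``influential_genus=True`` an extra genus of severely and erratically
    declining populations — declines unrelated to the predictor — is
    appended; its huge residual spread inflates the model's error variance
    and masks the otherwise-clear effect, so excluding that genus (and only
    that genus) changes the significance verdict.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genera):
        u = rng.normal(0.0, genus_sd)
        for p in range(populations_per_genus):
            x = rng.normal(0.0, 1.0)
            y = effect * x + u + rng.normal(0.0, residual_sd)
            rows.append(
                {
                    "population_id": f"P{g:03d}_{p:02d}",
                    "genus": f"G{g:03d}",
                    "predictor": x,
                    "avg_rate": y,
                }
            )
    if influential_genus:
        for p in range(populations_per_genus):
            rows.append(
                {
                    "population_id": f"GYPS_{p:02d}",
                    "genus": "Gyps-like",
                    "predictor": rng.normal(0.0, 1.0),
                    "avg_rate": rng.normal(-0.3, 50 * residual_sd),
                }
            )
    return pd.DataFrame(rows)
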