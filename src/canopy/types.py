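"""Core domain types for the forest-specialist index pipeline.

The central record is a :class:`PopulationSeries` — one monitored population's
abundance-by-year observations plus the taxonomy/geography tags needed for
aggregation (realm, taxonomic group, biome group) and for the correlates
analysis (location, genus, exploitation threat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TAXON_GROUPS = ("birds", "mammals", "herptiles")
REALMS = ("Nearctic", "Palaearctic", "Neotropical", "Afrotropical", "IndoPacific")
BIOME_GROUPS = ("temperate", "tropical", "other")

#: Buffer radius (km) used when the per-population covariates were extracted.
BUFFER_RADIUS_KM = 5.0
#: Area of the circular extraction buffer, km^2.
BUFFER_AREA_KM2 = 3.141592653589793 * BUFFER_RADIUS_KM**2


class CanopyError(Exception):
    """Base class for pipeline errors."""


class ValidationError(CanopyError):
    """Raised when an input table violates its contract."""


class PopulationExcluded(CanopyError):
    """Raised when a population cannot enter the analysis (e.g. all-zero counts)."""


@dataclass(frozen=True)
class PopulationSeries:
    """One population's abundance record.

    ``observations`` maps survey year to abundance in whatever consistent
    per-population survey unit the source used; only ratios of abundances are
    ever consumed downstream, so the unit cancels.
    """

    population_id: str
    species_id: str
    genus: str
    taxon_group: str
    realm: str
    biome_group: str
    specialist: bool
    location_id: str
    exploitation_primary_threat: bool
    observations: dict[int, float]
    family: str | None = None
    order: str | None = None

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValidationError(
                f"{self.population_id}: unknown taxon_group {self.taxon_group!r}"
            )
        if self.realm not in REALMS:
            raise ValidationError(f"{self.population_id}: unknown realm {self.realm!r}")
        if self.biome_group not in BIOME_GROUPS:
            raise ValidationError(
                f"{self.population_id}: unknown biome_group {self.biome_group!r}"
            )
        if len(self.observations) < 2:
            raise ValidationError(
                f"{self.population_id}: needs >=2 observation years, "
                f"got {len(self.observations)}"
            )
        years = list(self.observations)
        if years != sorted(years):
            raise ValidationError(f"{self.population_id}: years must be increasing")
        for year, value in self.observations.items():
            if value < 0:
                raise ValidationError(
                    f"{self.population_id}: negative abundance {value} in {year}"
                )

    @property
    def years(self) -> list[int]:
        return list(self.observations)

    @property
    def subset(self) -> tuple[str, str]:
        return (self.realm, self.taxon_group)


@dataclass(frozen=True)
class FittedSeries:
    """Annual fitted log10 abundance on every integer year of the observed span."""

    population_id: str
    method: str  # "gam" or "linear"
    fitted_log10: dict[int, float]
    zero_adjustment: float = 0.0

    def __post_init__(self) -> None:
        years = list(self.fitted_log10)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValidationError(
                f"{self.population_id}: fitted span must have no gaps"
            )


@dataclass(frozen=True)
class AnnualRates:
    """Capped annual log10 growth rates d_t = log10 N_t - log10 N_{t-1}.

    ``rates[t]`` is the (capped) change from year ``t-1`` to year ``t``.
    """

    population_id: str
    rates: dict[int, float]
    cap: float = 1.0


@dataclass(frozen=True)
class WeightingScheme:
    """Two-level diversity weights: realm, then taxon within realm.

    Weights are proportional to forest species richness and normalised over
    the subsets that actually hold time-series data.
    """

    realm_weights: dict[str, float]
    taxon_weights: dict[tuple[str, str], float]
    subsets: tuple[tuple[str, str], ...]

    def subset_weight(self, realm: str, taxon: str) -> float:
        return self.realm_weights[realm] * self.taxon_weights[(realm, taxon)]


@dataclass
class CompositeIndex:
    """Chained yearly index with bootstrap confidence bands.

    ``index[baseline_year] == 1`` and ``index[t] = index[t-1] * 10**dbar_t``
    where ``dbar_t`` is the diversity-weighted mean annual rate.
    """

    years: list[int]
    index: dict[int, float]
    ci_low: dict[int, float] = field(default_factory=dict)
    ci_high: dict[int, float] = field(default_factory=dict)
    n_species_per_year: dict[int, int] = field(default_factory=dict)

    @property
    def baseline_year(self) -> int:
        return self.years[0]

    @property
    def final_value(self) -> float:
        return self.index[self.years[-1]]


@dataclass(frozen=True)
class PopulationResponse:
    """A population's windowed average rate of change (correlates response)."""

    population_id: str
    window: str  # "song" or "hansen"
    study_period: tuple[int, int]
    avg_rate: float
    location_id: str
    genus: str
    specialist: bool


@dataclass(frozen=True)
class CoverCovariates:
    """Tree-cover summaries for one population's (lagged) study period."""

    population_id: str
    mean_tree_cover: float
    mean_bare_ground: float
    cover_trend: float
    cover_2000: float
    loss_area: float
    prop_change_2000_2010: float  # NaN when cover_2000 == 0


@dataclass(frozen=True)
class ModelComparison:
    """A univariate mixed model against the location-random-effect null."""

    predictor: str
    coefficient: float
    coefficient_se: float
    aic_model: float
    aic_null: float
    n_populations: int
    n_locations: int
    singular: bool = False
    subset: str = "all"

    @property
    def delta_aic(self) -> float:
        return self.aic_null - self.aic_model

    @property
    def significant(self) -> bool:
        return self.delta_aic >= 2.0
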