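import numpy as np
import pandas as pd
import pytest

from canopy import Scenario, generate_populations, generate_richness
from canopy.io import population_series_from_frame
from canopy.types import PopulationSeries


def make_series(
    observations: dict[int, float],
    population_id: str = "P1",
    species_id: str = "S1",
    realm: str = "Nearctic",
    taxon_group: str = "birds",
    **kwargs,
) -> PopulationSeries:
    defaults = dict(
        genus="G1",
        biome_group="temperate",
        specialist=True,
        location_id="L1",
        exploitation_primary_threat=False,
    )
    defaults.update(kwargs)
    return PopulationSeries(
        population_id=population_id,
        species_id=species_id,
        realm=realm,
        taxon_group=taxon_group,
        observations=observations,
        **defaults,
    )


def trend_frame(records: list[tuple]) -> pd.DataFrame:
    """Species-trend frame from (species, realm, taxon, biome, year, rate) rows."""
    return pd.DataFrame(
        records,
        columns=["species_id", "realm", "taxon_group", "biome_group", "year", "rate"],
    )


@pytest.fixture(scope="session")
def headline_scenario() -> Scenario:
    return Scenario.forest_specialists()


@pytest.fixture(scope="session")
def synthetic_tables(headline_scenario):
    """One seeded draw of the default scenario, shared across tests."""
    populations, truth = generate_populations(headline_scenario, seed=7)
    richness = generate_richness(headline_scenario)
    return populations, richness, truth


@pytest.fixture(scope="session")
def synthetic_series(synthetic_tables):
    populations, _, _ = synthetic_tables
    return population_series_from_frame(populations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
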