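import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopy import (
    annual_log_rates,
    bootstrap_ci,
    chain_index,
    compute_weights,
    implied_annual_change_percent,
    species_trends,
    subset_annual_rates,
)
from canopy.types import AnnualRates, CanopyError, FittedSeries, WeightingScheme

from conftest import make_series, trend_frame

REALMS5 = ("Nearctic", "Palaearctic", "Neotropical", "Afrotropical", "IndoPacific")


def richness_frame(entries):
    return pd.DataFrame(
        [
            {"realm": r, "taxon_group": t, "species_count": c}
            for (r, t), c in entries.items()
        ]
    )


def uniform_weights(subsets):
    realms = sorted({r for r, _ in subsets})
    taxa_per_realm = {r: [t for rr, t in subsets if rr == r] for r in realms}
    return WeightingScheme(
        realm_weights={r: 1.0 / len(realms) for r in realms},
        taxon_weights={
            (r, t): 1.0 / len(taxa_per_realm[r])
            for r in realms
            for t in taxa_per_realm[r]
        },
        subsets=tuple(sorted(subsets)),
    )


class TestComputeWeights:
    def test_fourteen_subsets_with_renormalised_palaearctic(self):
        entries = {
            (r, t): 100
            for r in REALMS5
            for t in ("birds", "mammals", "herptiles")
        }
        subsets = [
            (r, t)
            for r in REALMS5
            for t in ("birds", "mammals", "herptiles")
            if not (r == "Palaearctic" and t == "herptiles")
        ]
        weights = compute_weights(richness_frame(entries), subsets)
        assert len(weights.subsets) == 14
        # Palaearctic taxon weights renormalise over birds+mammals only
        assert weights.taxon_weights[("Palaearctic", "birds")] == pytest.approx(0.5)
        assert weights.taxon_weights[("Palaearctic", "mammals")] == pytest.approx(0.5)
        assert ("Palaearctic", "herptiles") not in weights.taxon_weights
        assert sum(weights.realm_weights.values()) == pytest.approx(1.0)

    def test_taxon_weights_proportional_to_richness(self):
        entries = {
            ("Nearctic", "birds"): 300,
            ("Nearctic", "mammals"): 100,
            ("Nearctic", "herptiles"): 100,
        }
        weights = compute_weights(richness_frame(entries), list(entries))
        assert weights.taxon_weights[("Nearctic", "birds")] == pytest.approx(0.6)
        assert weights.taxon_weights[("Nearctic", "mammals")] == pytest.approx(0.2)
        assert weights.taxon_weights[("Nearctic", "herptiles")] == pytest.approx(0.2)

    def test_equal_counts_give_equal_weights(self):
        entries = {(r, "birds"): 50 for r in REALMS5}
        weights = compute_weights(richness_frame(entries), list(entries))
        for w in weights.realm_weights.values():
            assert w == pytest.approx(0.2)

    def test_subset_missing_from_richness_is_fatal(self):
        entries = {("Nearctic", "birds"): 50}
        with pytest.raises(CanopyError, match="missing"):
            compute_weights(
                richness_frame(entries),
                [("Nearctic", "birds"), ("Nearctic", "mammals")],
            )


class TestSpeciesTrends:
    def test_opposite_population_rates_average_to_zero(self):
        series = [
            make_series({2000: 1, 2001: 1}, population_id=p, species_id="S1")
            for p in ("P1", "P2")
        ]
        rates = {
            "P1": AnnualRates("P1", {2001: -0.1}),
            "P2": AnnualRates("P2", {2001: +0.1}),
        }
        trends = species_trends(rates, series)
        assert trends.loc[0, "rate"] == pytest.approx(0.0)

    def test_single_population_species_is_identity(self):
        series = [make_series({2000: 1, 2002: 1})]
        rates = {"P1": AnnualRates("P1", {2001: -0.05, 2002: 0.02})}
        trends = species_trends(rates, series)
        assert dict(zip(trends["year"], trends["rate"])) == pytest.approx(
            {2001: -0.05, 2002: 0.02}
        )

    def test_three_population_mean(self):
        series = [
            make_series({2000: 1, 2001: 1}, population_id=p, species_id="S1")
            for p in ("P1", "P2", "P3")
        ]
        rates = {
            p: AnnualRates(p, {2001: d})
            for p, d in zip(("P1", "P2", "P3"), (-0.3, -0.3, 0.3))
        }
        trends = species_trends(rates, series)
        assert trends.loc[0, "rate"] == pytest.approx(-0.1)


class TestSubsetAnnualRates:
    def test_mean_across_species(self):
        trends = trend_frame(
            [
                ("S1", "Nearctic", "birds", "temperate", 2001, -0.02),
                ("S2", "Nearctic", "birds", "temperate", 2001, 0.0),
            ]
        )
        rates = subset_annual_rates(trends, ("Nearctic", "birds"))
        assert rates[2001] == pytest.approx(-0.01)

    def test_species_leaving_mid_series_drops_from_mean(self):
        trends = trend_frame(
            [
                ("S1", "Nearctic", "birds", "temperate", 2001, -0.1),
                ("S1", "Nearctic", "birds", "temperate", 2002, -0.1),
                ("S2", "Nearctic", "birds", "temperate", 2001, 0.1),
            ]
        )
        rates = subset_annual_rates(trends, ("Nearctic", "birds"))
        assert rates[2001] == pytest.approx(0.0)
        assert rates[2002] == pytest.approx(-0.1)


class TestChainIndex:
    def test_zero_rates_give_flat_unit_index(self):
        trends = trend_frame(
            [("S1", "Nearctic", "birds", "temperate", y, 0.0) for y in range(1971, 2015)]
        )
        composite = chain_index(trends, uniform_weights([("Nearctic", "birds")]))
        assert all(v == pytest.approx(1.0) for v in composite.index.values())

    def test_constant_decline_matches_closed_form(self):
        """44 annual steps of log10(0.983) chain to 0.983**44 ~ 0.47."""
        rate = np.log10(0.983)
        trends = trend_frame(
            [("S1", "Nearctic", "birds", "temperate", y, rate) for y in range(1971, 2015)]
        )
        composite = chain_index(trends, uniform_weights([("Nearctic", "birds")]))
        assert composite.final_value == pytest.approx(0.983**44, rel=1e-9)
        assert composite.final_value == pytest.approx(0.47, abs=0.005)

    def test_two_opposed_subsets_cancel(self):
        rows = []
        for year in range(1971, 2015):
            rows.append(("S1", "Nearctic", "birds", "temperate", year, +0.1))
            rows.append(("S2", "Nearctic", "mammals", "temperate", year, -0.1))
        weights = uniform_weights([("Nearctic", "birds"), ("Nearctic", "mammals")])
        composite = chain_index(trend_frame(rows), weights)
        for value in composite.index.values():
            assert value == pytest.approx(1.0)

    def test_single_chain_equals_cumsum_oracle(self, rng):
        """One population's index is 10**(cumulative sum of capped rates)."""
        fitted = FittedSeries(
            "P1",
            "linear",
            {1970 + i: float(v) for i, v in enumerate(rng.normal(2, 0.5, 45))},
        )
        rates = annual_log_rates(fitted, cap=1.0)
        series = [make_series({1970: 1, 2014: 1})]
        trends = species_trends({"P1": rates}, series)
        composite = chain_index(trends, uniform_weights([("Nearctic", "birds")]))
        expected = 10.0 ** np.cumsum([rates.rates[y] for y in range(1971, 2015)])
        observed = [composite.index[y] for y in range(1971, 2015)]
        np.testing.assert_allclose(observed, expected, rtol=1e-9)

    def test_permutation_invariance(self, rng):
        rows = [
            (f"S{i}", "Nearctic", "birds", "temperate", year, float(rng.normal(0, 0.05)))
            for i in range(5)
            for year in range(1971, 1990)
        ]
        trends = trend_frame(rows)
        weights = uniform_weights([("Nearctic", "birds")])
        shuffled = trends.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = chain_index(trends, weights, final_year=1989)
        b = chain_index(shuffled, weights, final_year=1989)
        assert a.index == pytest.approx(b.index)

    def test_no_baseline_data_is_fatal(self):
        trends = trend_frame(
            [("S1", "Nearctic", "birds", "temperate", 1990, -0.1)]
        )
        with pytest.raises(CanopyError, match="baseline"):
            chain_index(trends, uniform_weights([("Nearctic", "birds")]))

    def test_yearly_weight_renormalisation_over_data_bearing_subsets(self):
        # birds decline every year; mammals only have data in 1972
        rows = [
            ("S1", "Nearctic", "birds", "temperate", 1971, -0.1),
            ("S1", "Nearctic", "birds", "temperate", 1972, -0.1),
            ("S2", "Nearctic", "mammals", "temperate", 1972, 0.1),
        ]
        weights = uniform_weights([("Nearctic", "birds"), ("Nearctic", "mammals")])
        composite = chain_index(trend_frame(rows), weights, final_year=1972)
        # 1971: birds only -> full weight on birds; 1972: split 50/50 -> dbar 0
        assert composite.index[1971] == pytest.approx(10.0**-0.1)
        assert composite.index[1972] == pytest.approx(10.0**-0.1)


class TestBootstrap:
    def test_identical_species_give_zero_width_band(self):
        rows = [
            (s, "Nearctic", "birds", "temperate", year, -0.01)
            for s in ("S1", "S2", "S3")
            for year in range(1971, 1981)
        ]
        weights = uniform_weights([("Nearctic", "birds")])
        low, high = bootstrap_ci(
            trend_frame(rows), weights, n_boot=100, seed=0, final_year=1980
        )
        for year in range(1970, 1981):
            assert low[year] == pytest.approx(high[year])

    def test_fixed_seed_reproducible(self, rng):
        rows = [
            (f"S{i}", "Nearctic", "birds", "temperate", year, float(rng.normal(0, 0.02)))
            for i in range(8)
            for year in range(1971, 1981)
        ]
        weights = uniform_weights([("Nearctic", "birds")])
        first = bootstrap_ci(trend_frame(rows), weights, n_boot=100, seed=42, final_year=1980)
        second = bootstrap_ci(trend_frame(rows), weights, n_boot=100, seed=42, final_year=1980)
        assert first == second

    def test_point_estimate_within_bands(self, rng):
        rows = [
            (f"S{i}", "Nearctic", "birds", "temperate", year, float(rng.normal(-0.005, 0.03)))
            for i in range(40)
            for year in range(1971, 2001)
        ]
        trends = trend_frame(rows)
        weights = uniform_weights([("Nearctic", "birds")])
        composite = chain_index(trends, weights, final_year=2000)
        low, high = bootstrap_ci(trends, weights, n_boot=300, seed=1, final_year=2000)
        for year in composite.index:
            assert low[year] <= composite.index[year] <= high[year]


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_weight_conservation_every_year(seed):
    """Effective subset weights sum to 1 in every year under renormalisation."""
    rng = np.random.default_rng(seed)
    subsets = [("Nearctic", "birds"), ("Nearctic", "mammals"), ("Neotropical", "birds")]
    rows = []
    for i, (realm, taxon) in enumerate(subsets):
        start = 1971 if i == 0 else 1971 + int(rng.integers(0, 5))
        stop = 1980 - int(rng.integers(0, 5))
        for year in range(start, max(start + 1, stop)):
            rows.append((f"S{i}", realm, taxon, "temperate", year, 0.013))
    trends = trend_frame(rows)
    weights = uniform_weights(subsets)
    composite = chain_index(trends, weights, final_year=1980)
    # constant rate everywhere: any correctly normalised weighting yields
    # exactly that rate in data-bearing years and 0 in empty years
    for prev, year in zip(composite.years, composite.years[1:]):
        step = np.log10(composite.index[year] / composite.index[prev])
        assert step == pytest.approx(0.013) or step == pytest.approx(0.0)


def test_implied_annual_change_percent_closed_form():
    assert implied_annual_change_percent(0.47, 44) == pytest.approx(1.7, abs=0.05)
    assert implied_annual_change_percent(0.59, 44) == pytest.approx(1.2, abs=0.05)
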