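"""Disaggregate the index: declining shares, group means, dataset turnover.

A composite index can fall because species decline — or drift because data
series enter and leave the monitored set.  These diagnostics separate the
two readings.
"""

import dataclasses

from canopy import (
    Scenario,
    generate_populations,
    group_mean_rates,
    percent_declining_by_year,
    population_series_from_frame,
    species_overall_rates,
    species_trends,
    turnover,
)
from canopy.trends import population_rates

# heterogeneous trends: population rates scattered around a mild decline
scenario = dataclasses.replace(Scenario.forest_specialists(), sigma_rate=0.02)
populations, _ = generate_populations(scenario, seed=5)
series = population_series_from_frame(populations)
rates, _ = population_rates(series)
trends = species_trends(rates, series)

shares = percent_declining_by_year(trends)
recent = shares[shares["year"].between(2005, 2010)]
print("share of species declining, 2005-2010:")
print(recent[["year", "pct_declining", "n_species"]].to_string(index=False))

overall = species_overall_rates(trends)
print("\nmean overall rate per taxonomic group (+/- SE):")
print(group_mean_rates(overall, "taxon_group").to_string(index=False))

report = turnover(trends, (2000, 2002))
print("\nspecies entering/leaving the dataset in 2000-2002, by trend sign:")
print(report.to_string(index=False))
# Entering increasers and leaving decliners can slow an index's fall without
# any real recovery; the turnover table makes that bookkeeping explicit.
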