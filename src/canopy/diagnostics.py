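"""Disaggregation diagnostics for the composite index.

Composite abundance indices can move because species genuinely decline or
recover, but also because the monitored set itself changes — data series
entering or leaving mid-index.  These helpers expose the per-year share of
declining species, group-level mean rates with standard errors, and
dataset-turnover accounting over a year window.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import CanopyError

GROUPINGS = ("taxon_group", "realm", "biome_group")


def percent_declining(trends: pd.DataFrame, year: int) -> float:
    """Share of species with a strictly negative annual mean rate in ``year``.

    Ties at exactly zero count as neither declining nor increasing.
    """
    rates = trends.loc[trends["year"] == year, "rate"]
    if rates.empty:
        raise CanopyError(f"no species has a rate in {year}")
    return float((rates < 0).mean())


def percent_declining_by_year(trends: pd.DataFrame) -> pd.DataFrame:
    """Per-year declining / increasing / zero fractions over all species."""
    def _shares(group: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "pct_declining": float((group < 0).mean()),
                "pct_increasing": float((group > 0).mean()),
                "pct_zero": float((group == 0).mean()),
                "n_species": int(group.size),
            }
        )

    out = trends.groupby("year")["rate"].apply(_shares).unstack().reset_index()
    out["n_species"] = out["n_species"].astype(int)
    return out


def group_mean_rates(
    species_rates: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Mean overall species rate +/- standard error per group.

    ``species_rates`` is the output of
    :func:`canopy.index.species_overall_rates`.  SE is the sample standard
    deviation over sqrt(n); with a single species it is undefined (NaN).
    """
    if grouping not in GROUPINGS:
        raise CanopyError(f"unknown grouping {grouping!r}; use one of {GROUPINGS}")
    rows = []
    for group, sub in species_rates.groupby(grouping):
        n = len(sub)
        mean = float(sub["overall_rate"].mean())
        se = float(sub["overall_rate"].std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan
        rows.append({"group": group, "mean_rate": mean, "se": se, "n_species": n})
    return pd.DataFrame(rows)


def turnover(trends: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Species entering and leaving the dataset within ``window``.

    A species *enters* if its first rate-year falls inside the (inclusive)
    window and *leaves* if its last rate-year does; each count is split by
    the sign of the species' overall rate.  A species spanning the whole
    window is counted in neither direction.
    """
    start, end = window
    if start > end:
        raise CanopyError(f"invalid window {window}")
    key = ["species_id", "realm", "taxon_group"]
    spans = trends.groupby(key).agg(
        first_year=("year", "min"),
        last_year=("year", "max"),
        overall_rate=("rate", "mean"),
    )

    def _split(mask: pd.Series) -> dict[str, int]:
        rates = spans.loc[mask, "overall_rate"]
        return {
            "declining": int((rates < 0).sum()),
            "increasing": int((rates > 0).sum()),
            "stable": int((rates == 0).sum()),
        }

    entering = _split(spans["first_year"].between(start, end))
    leaving = _split(spans["last_year"].between(start, end))
    rows = [
        {"direction": "entering", **entering},
        {"direction": "leaving", **leaving},
    ]
    return pd.DataFrame(rows)
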