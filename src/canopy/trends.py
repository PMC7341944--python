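"""Per-population trend fitting: annual fitted log10 abundance and capped rates.

Each population's raw abundance series is converted to annual fitted log10
abundances over the observed span — a GAM-style penalized spline when at
least 6 survey years are available, an ordinary least-squares line for 2–5
years — and then to annual log10 growth rates
``d_t = fitted_log10(t) - fitted_log10(t-1)``, capped at ±1 (a tenfold annual
change) by convention.  Zero counts are handled before logging by adding 1%
of the mean of the non-zero observations to every observation.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .smoothing import fit_pspline
from .types import AnnualRates, FittedSeries, PopulationExcluded, PopulationSeries

log = logging.getLogger(__name__)

#: Minimum number of survey years for the spline (GAM) path.
GAM_MIN_OBS = 6
#: Default cap on |d_t| in log10 units (tenfold annual change).
DEFAULT_CAP = 1.0


def adjust_zeros(series: PopulationSeries) -> tuple[dict[int, float], float]:
    """Return zero-adjusted observations and the adjustment applied.

    If any observed abundance is exactly zero, 1% of the mean of the non-zero
    observations is added to *every* observation so the series can be logged;
    otherwise the series is returned unchanged.  An all-zero series carries no
    trend information and is excluded.
    """
    values = np.array(list(series.observations.values()), dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise PopulationExcluded(
            f"{series.population_id}: all observations are zero"
        )
    if (values == 0).any():
        adjustment = 0.01 * float(nonzero.mean())
        adjusted = {y: v + adjustment for y, v in series.observations.items()}
        return adjusted, adjustment
    return dict(series.observations), 0.0


def fit_population_model(
    series: PopulationSeries, gam_min_obs: int = GAM_MIN_OBS
) -> FittedSeries:
    """Fit log10 abundance on year and predict on every year of the span.

    Spline path (n >= ``gam_min_obs``): penalized B-spline with basis
    dimension ceil(n/2) and GCV-chosen smoothing; falls back to the linear
    path (with a warning) if the smoother fails.  Linear path (2 <= n < 6):
    OLS line through (year, log10 abundance).  No extrapolation beyond the
    observed span.
    """
    observations, adjustment = adjust_zeros(series)
    years = np.array(list(observations), dtype=float)
    logged = np.log10(np.array(list(observations.values()), dtype=float))
    grid = np.arange(int(years[0]), int(years[-1]) + 1)

    n = years.size
    method = "gam" if n >= gam_min_obs else "linear"
    fitted = None
    if method == "gam":
        try:
            fit = fit_pspline(years, logged, n_basis=math.ceil(n / 2))
            fitted = fit.predict(grid)
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            log.warning(
                "%s: smoother failed (%s); falling back to linear fit",
                series.population_id,
                exc,
            )
            method = "linear"
    if fitted is None:
        slope, intercept = np.polyfit(years, logged, 1)
        fitted = intercept + slope * grid

    return FittedSeries(
        population_id=series.population_id,
        method=method,
        fitted_log10={int(y): float(v) for y, v in zip(grid, fitted)},
        zero_adjustment=adjustment,
    )


def annual_log_rates(fitted: FittedSeries, cap: float = DEFAULT_CAP) -> AnnualRates:
    """Difference consecutive fitted log10 values and clip to ±cap."""
    years = list(fitted.fitted_log10)
    rates = {}
    for prev, year in zip(years, years[1:]):
        d = fitted.fitted_log10[year] - fitted.fitted_log10[prev]
        rates[year] = float(np.clip(d, -cap, cap))
    return AnnualRates(population_id=fitted.population_id, rates=rates, cap=cap)


def population_rates(
    series_list: list[PopulationSeries],
    cap: float = DEFAULT_CAP,
    gam_min_obs: int = GAM_MIN_OBS,
) -> tuple[dict[str, AnnualRates], list[str]]:
    """Fit every population; return rates by id and the ids excluded (all-zero)."""
    rates: dict[str, AnnualRates] = {}
    excluded: list[str] = []
    for series in series_list:
        try:
            fitted = fit_population_model(series, gam_min_obs=gam_min_obs)
        except PopulationExcluded as exc:
            log.info("excluded: %s", exc)
            excluded.append(series.population_id)
            continue
        rates[series.population_id] = annual_log_rates(fitted, cap=cap)
    return rates, excluded
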