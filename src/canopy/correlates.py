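"""Correlates of population change: windowed rates, cover covariates, mixed models.

The response is each population's average annual log10 rate of change over a
satellite-era window — 1982–2016 when paired with the long-term fractional
tree-cover product ("song"), 2000–2015 with the 30 m forest-change product
("hansen").  Predictors are buffer-level tree-cover summaries, below-canopy
pressures (exploitation threat, road density, human population density,
travel time) and log10 body mass.  Each predictor is tested in a univariate
linear mixed model with a location random intercept, fitted by maximum
likelihood, against the intercept-only null; a predictor is called
significant when it lowers the AIC by at least 2.  An influence analysis
refits each predictor with a genus random effect, dropping one genus at a
time, and flags genera whose exclusion moves the fixed effect across the
|z| = 1.96 line.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .smoothing import fit_pspline
from .trends import GAM_MIN_OBS
from .types import (
    AnnualRates,
    BUFFER_AREA_KM2,
    CanopyError,
    CoverCovariates,
    ModelComparison,
    PopulationResponse,
    PopulationSeries,
)

log = logging.getLogger(__name__)

#: Analysis windows (inclusive year ranges) named after the tree-cover product.
WINDOWS = {"song": (1982, 2016), "hansen": (2000, 2015)}

#: Minimum span (last - first rate-year) — "2 years over at least a 5-year period".
MIN_SPAN = 4

CONTINUOUS_PREDICTORS = (
    "mean_tree_cover",
    "mean_bare_ground",
    "cover_trend",
    "cover_2000",
    "loss_area",
    "prop_change_2000_2010",
    "log_body_mass",
    "road_density",
    "hpd",
    "travel_time",
)
BINARY_PREDICTORS = ("exploitation",)


def windowed_response(
    rates: AnnualRates,
    window: str,
    series: PopulationSeries,
) -> PopulationResponse | None:
    """Average rate of change over the window, or ``None`` if the population fails
    the 2-year / 5-year-span retention rule.

    Rate-years are clipped to the window; the population is retained only if
    at least two rate-years remain and they span at least five calendar years
    (last - first >= 4).
    """
    start, end = WINDOWS[window]
    years = sorted(t for t in rates.rates if start < t <= end)
    if len(years) < 2 or years[-1] - years[0] < MIN_SPAN:
        return None
    avg = float(np.mean([rates.rates[t] for t in years]))
    return PopulationResponse(
        population_id=rates.population_id,
        window=window,
        study_period=(years[0], years[-1]),
        avg_rate=avg,
        location_id=series.location_id,
        genus=series.genus,
        specialist=series.specialist,
    )


def smooth_cover_series(
    annual_cover: dict[int, float],
    buffer_area: float = BUFFER_AREA_KM2,
    gam_min_obs: int = GAM_MIN_OBS,
) -> dict[int, float]:
    """Smooth an annual tree-cover series on its own (untransformed) scale.

    Same smoother contract as the population fits — penalized spline from six
    values, straight line below — with fitted values clipped to the physical
    range [0, buffer area].
    """
    items = [(y, v) for y, v in sorted(annual_cover.items()) if not np.isnan(v)]
    if len(items) < 2:
        raise CanopyError("cover series needs at least two non-missing values")
    years = np.array([y for y, _ in items], dtype=float)
    values = np.array([v for _, v in items], dtype=float)
    grid = np.arange(int(years[0]), int(years[-1]) + 1)
    if years.size >= gam_min_obs:
        try:
            fitted = fit_pspline(
                years, values, n_basis=int(np.ceil(years.size / 2))
            ).predict(grid)
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            slope, intercept = np.polyfit(years, values, 1)
            fitted = intercept + slope * grid
    else:
        slope, intercept = np.polyfit(years, values, 1)
        fitted = intercept + slope * grid
    fitted = np.clip(fitted, 0.0, buffer_area)
    return {int(y): float(v) for y, v in zip(grid, fitted)}


def derive_cover_covariates(
    population_id: str,
    fitted_cover: dict[int, float],
    bare_ground: dict[int, float],
    loss: dict[int, float],
    study_period: tuple[int, int],
    cover_2000: float,
    cover_2010: float,
    lag: int = 1,
) -> CoverCovariates:
    """Summarise cover series over a population's (lagged) study period.

    Cover in year t is paired with population data in year t + ``lag``, so
    means and the OLS trend are taken over cover years
    [first - lag, last - lag].  Loss is summed over the unlagged study period.
    A population whose fitted cover is zero throughout is excluded.
    """
    first, last = study_period
    lag_years = [t for t in range(first - lag, last - lag + 1) if t in fitted_cover]
    if not lag_years:
        raise CanopyError(
            f"{population_id}: no cover data over lagged period "
            f"{first - lag}-{last - lag}"
        )
    cover_vals = np.array([fitted_cover[t] for t in lag_years], dtype=float)
    if np.all(np.asarray(list(fitted_cover.values())) == 0.0):
        raise CanopyError(f"{population_id}: zero tree cover in all years")

    slope = (
        float(np.polyfit(lag_years, cover_vals, 1)[0]) if len(lag_years) > 1 else 0.0
    )
    bare_vals = [
        bare_ground[t]
        for t in lag_years
        if t in bare_ground and not np.isnan(bare_ground[t])
    ]
    loss_area = float(
        sum(v for t, v in loss.items() if first <= t <= last and not np.isnan(v))
    )
    if cover_2000 > 0:
        prop_change = (cover_2010 - cover_2000) / cover_2000
    else:
        prop_change = np.nan
        log.info("%s: cover_2000 is zero; proportional change undefined", population_id)

    return CoverCovariates(
        population_id=population_id,
        mean_tree_cover=float(cover_vals.mean()),
        mean_bare_ground=float(np.mean(bare_vals)) if bare_vals else np.nan,
        cover_trend=slope,
        cover_2000=float(cover_2000),
        loss_area=loss_area,
        prop_change_2000_2010=float(prop_change),
    )


def impute_body_mass(
    static: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.Series:
    """Impute missing species body mass from genus, then family, then order means.

    ``static`` carries ``population_id`` and ``body_mass_g``; ``taxonomy``
    maps population_id to genus/family/order.  Returns body mass in grams
    indexed like ``static`` (NaN where no rank holds data).
    """
    frame = static.merge(taxonomy, on="population_id", how="left")
    mass = frame["body_mass_g"].astype(float).copy()
    for rank in ("genus", "family", "order"):
        if rank not in frame.columns:
            continue
        rank_mean = frame.groupby(rank)["body_mass_g"].transform("mean")
        mass = mass.fillna(rank_mean)
    mass.index = static.index
    return mass


def prepare_predictors(
    responses: pd.DataFrame,
    covariates: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the model frame: response + standardized predictors.

    Continuous predictors are z-scored over the populations entering the
    analysis; the exploitation flag stays binary; the response is left in its
    natural units (log10 yr^-1).  Missing values are preserved and handled
    per-model by casewise deletion.
    """
    if covariates is None or covariates.empty:
        frame = responses.copy()
    else:
        frame = responses.merge(covariates, on="population_id", how="left")
    if taxonomy is not None and "body_mass_g" in frame.columns:
        frame["body_mass_g"] = impute_body_mass(
            frame[["population_id", "body_mass_g"]], taxonomy
        )
    if "body_mass_g" in frame.columns:
        with np.errstate(divide="ignore"):
            frame["log_body_mass"] = np.log10(frame["body_mass_g"].astype(float))
    for name in CONTINUOUS_PREDICTORS:
        if name not in frame.columns:
            continue
        values = frame[name].astype(float)
        sd = values.std(ddof=0)
        if sd > 0:
            frame[name] = (values - values.mean()) / sd
    return frame


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, data, groups=groups)
        return model.fit(reml=False)


def fit_univariate_mixed(
    model_frame: pd.DataFrame,
    predictor: str,
    grouping: str = "location_id",
    response: str = "avg_rate",
    subset_label: str = "all",
) -> ModelComparison:
    """Random-intercept model for one predictor vs. the null, compared by AIC.

    Both models are fitted by maximum likelihood (AIC comparisons across
    fixed-effect structures require ML, not REML).  Rows missing the
    predictor or response are dropped for both fits, so the comparison is on
    a common dataset.  A near-zero random-effect variance is reported with a
    ``singular`` flag but does not invalidate the comparison.
    """
    data = model_frame.dropna(subset=[predictor, response, grouping]).copy()
    if data[predictor].nunique() < 2:
        raise CanopyError(f"predictor {predictor!r} is constant")
    if data[grouping].nunique() < 2:
        raise CanopyError("need at least two locations for a random effect")

    fit = _fit_mixedlm(f"{response} ~ {predictor}", data, data[grouping])
    null = _fit_mixedlm(f"{response} ~ 1", data, data[grouping])
    singular = bool(np.asarray(fit.cov_re).max() < 1e-8)
    if singular:
        log.info("%s: random-effect variance estimated at zero", predictor)
    return ModelComparison(
        predictor=predictor,
        coefficient=float(fit.params[predictor]),
        coefficient_se=float(fit.bse[predictor]),
        aic_model=float(fit.aic),
        aic_null=float(null.aic),
        n_populations=int(len(data)),
        n_locations=int(data[grouping].nunique()),
        singular=singular,
        subset=subset_label,
    )


def compare_all_predictors(
    model_frame: pd.DataFrame,
    predictors: list[str] | None = None,
    grouping: str = "location_id",
    subset_label: str = "all",
) -> pd.DataFrame:
    """Univariate comparisons for every available predictor, as a tidy frame."""
    if predictors is None:
        predictors = [
            p
            for p in (*CONTINUOUS_PREDICTORS, *BINARY_PREDICTORS)
            if p in model_frame.columns
        ]
    rows = []
    for predictor in predictors:
        try:
            comp = fit_univariate_mixed(
                model_frame, predictor, grouping=grouping, subset_label=subset_label
            )
        except CanopyError as exc:
            log.warning("skipping %s: %s", predictor, exc)
            continue
        rows.append(
            {
                "predictor": comp.predictor,
                "subset": comp.subset,
                "coefficient": comp.coefficient,
                "se": comp.coefficient_se,
                "aic_model": comp.aic_model,
                "aic_null": comp.aic_null,
                "delta_aic": comp.delta_aic,
                "significant": comp.significant,
                "singular": comp.singular,
                "n_populations": comp.n_populations,
                "n_locations": comp.n_locations,
            }
        )
    return pd.DataFrame(rows)


def genus_influence(
    model_frame: pd.DataFrame,
    predictors: list[str],
    response: str = "avg_rate",
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Leave-one-genus-out influence analysis with genus as the random effect.

    For each predictor, the full model is refitted excluding one genus at a
    time; a genus is flagged when the fixed-effect |z| crosses the
    significance line (``z_threshold``) in either direction relative to the
    full fit.  Exclusions that would leave fewer than two genera are skipped.
    """
    rows = []
    for predictor in predictors:
        data = model_frame.dropna(subset=[predictor, response, "genus"])
        genera = sorted(data["genus"].unique())
        if len(genera) < 3:
            raise CanopyError("influence analysis needs at least 3 genera")
        full = _fit_mixedlm(f"{response} ~ {predictor}", data, data["genus"])
        z_full = float(full.params[predictor] / full.bse[predictor])
        for genus in genera:
            kept = data[data["genus"] != genus]
            if kept["genus"].nunique() < 2:
                log.warning("excluding %s leaves <2 genera; skipped", genus)
                continue
            refit = _fit_mixedlm(
                f"{response} ~ {predictor}", kept, kept["genus"]
            )
            z_excl = float(refit.params[predictor] / refit.bse[predictor])
            flagged = (abs(z_full) >= z_threshold) != (abs(z_excl) >= z_threshold)
            rows.append(
                {
                    "predictor": predictor,
                    "genus": genus,
                    "z_full": z_full,
                    "z_excluded": z_excl,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)
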