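# Methods

This note records the statistical model behind `canopy`, the choices made
where the method leaves room, and what the synthetic-data tests do and do
not establish.

## Population trend model

Each population contributes an abundance-by-year record in arbitrary but
consistent survey units; only ratios of abundances ever enter the analysis,
so units cancel.  Zeros are handled before logging: if any observation is
exactly zero, 1 % of the mean of the non-zero observations is added to
*every* observation (a standard convention for log-scale composite
indices); all-zero series carry no trend information and are excluded with
a diagnostic.

Series with at least 6 survey years are smoothed with a generalized
additive model of log10 abundance on year; series with 2–5 years get an
ordinary least-squares line.  The smoother is a penalized B-spline
(P-spline): a cubic B-spline basis of dimension ⌈n/2⌉ on *uniform knots
extended past the observed span*, a second-order difference penalty on the
coefficients, and the penalty weight chosen by minimising the generalized
cross-validation score over a 41-point log-spaced grid (10⁻⁸…10⁸).  Two
properties of this construction matter:

- With uniform extended knots the difference penalty's null space contains
  constant and linear functions exactly, so a log-linear trend is
  reproduced to machine precision at any penalty weight and — crucially —
  the smoother does not distort trends at the span edges.  (With clamped
  boundary knots the null space bends near the boundary and we measured a
  systematic ~6 % steepening of fitted declines; the uniform-knot basis
  removes it.)
- At zero penalty the fit reduces to a regression spline of modest rank, so
  the basis dimension ⌈n/2⌉ (floored at 4, the minimum for a cubic basis)
  caps flexibility the way the k-argument of a conventional GAM does.

On a frozen noisy test series the fitted values agree with an independent
mgcv GAM (thin-plate basis, GCV) to 10⁻³ — both effectively select the
linear sub-model there.  Fitted values are predicted on every integer year
of the observed span, never beyond it.  If the smoother fails numerically
the population falls back to the linear path with a warning.

Annual rates are `d_t = fitted_log10(t) − fitted_log10(t−1)`, clipped to
±1 (at most a tenfold change per year, configurable).  Uncapped rates
telescope exactly to the fitted endpoint difference; rates are invariant to
rescaling abundance by any positive constant.

## Composite index

Rates are averaged arithmetically: populations → species (per year),
species → subset (per year), where a subset is one biogeographic realm ×
taxonomic group cell (14 populated cells in the default layout; Palaearctic
herptiles hold no data).  Subsets are combined with two-level diversity
weights: realm weights proportional to each realm's total forest species
richness, taxon weights within a realm proportional to that taxon's
richness renormalised over the taxa holding data.  Weights are renormalised
*each year* over the subsets with data that year; a year with no data
anywhere leaves the index flat rather than carrying a stale rate forward.
The chain is `I_t = I_{t−1} · 10^{d̄_t}` with `I_1970 = 1` (baseline and
final year 2014 configurable); a baseline year with no data at all is a
fatal error with advice to move the baseline.

Confidence bands resample *species* (the unit the index averages over)
with replacement within each subset, re-chain, and take per-year 2.5/97.5
percentiles (B = 1000 by default, seeded).  Percentile rather than
bias-corrected intervals were chosen for transparency; a subset with a
single species contributes a degenerate resample and is warned about.

The closed-form link between a final index value I after n annual steps and
a constant annual decline, `100·(1 − I^{1/n})` percent per year, is exposed
as a helper (0.47 over 44 steps ↔ 1.7 %/yr; 0.59 ↔ 1.2 %/yr).

## Diagnostics

Per year: the share of species with strictly negative annual mean rate
(exact zeros are counted separately, so declining + increasing + zero = 1).
Per grouping (taxon, realm, biome group): mean overall species rate with
SE = sd/√n (undefined for singleton groups).  Turnover accounting: a
species *enters* in a window if its first rate-year falls inside it,
*leaves* if its last does, each split by the sign of its overall rate —
the bookkeeping needed to tell genuine recovery from composition drift.

## Correlates analysis

The response is each population's arithmetic mean of annual rates over a
window — "song" (1982–2016, long-term fractional-cover product) or
"hansen" (2000–2015, 30 m forest-change product).  A rate-year t describes
the change from t−1 to t, so rate-years are clipped to (window start,
window end]; populations are retained only with ≥ 2 rate-years spanning at
least 5 calendar years (last − first ≥ 4).

Annual buffer tree-cover series are smoothed with the same smoother on the
untransformed scale and clipped to [0, π·5² km²]; summaries are taken over
the study period with a 1-year lag (cover in year t paired with population
data in t+1): mean cover, mean bare ground, and the OLS slope of fitted
cover on year.  From the high-resolution product: cover in 2000, loss
summed over the study period, and proportional 2000–2010 change (undefined
and flagged when cover in 2000 is zero).  Populations with zero cover
throughout are removed.  Body mass is imputed genus → family → order, then
log10-transformed; continuous predictors are z-scored over the populations
entering the models; the exploitation flag stays binary.

Each predictor is fitted alone in a linear mixed model with a location
random intercept, by maximum likelihood (REML is invalid for AIC
comparisons across fixed-effect structures), against the intercept-only
null on the same casewise-deleted rows; `ΔAIC = AIC_null − AIC_model ≥ 2`
is the significance rule.  Near-zero random-effect variance is reported
with a singular flag but does not invalidate the comparison.  Models are
fitted for all populations and for the specialist-only subset (predictors
re-standardised within the subset).

The influence analysis refits each predictor with *genus* as the random
effect (matching the grouping used for influence in the source workflow,
which differs deliberately from the location grouping of the main models),
excluding one genus at a time, and flags a genus when the fixed-effect |z|
crosses 1.96 in either direction relative to the full fit.

## Synthetic data

The generator emulates the structure the pipeline consumes, not any real
place: abundances follow `N_t = N_0 · 10^{r·t} · exp(ε_t)` with population
rate r ~ Normal(μ, σ_rate) (optionally shifted by δ for exploited
populations) and lognormal observation noise ε ~ N(0, σ_obs²);
interior survey years drop out independently (endpoints always kept, so
every series stays usable); buffer cover series are linear trends plus
AR(1) noise clipped to the physical range, with loss as the year-on-year
cover decrease; locations are shared between populations (~1.8 populations
per location).  Ground-truth sidecars (true rate per population, true cover
slope per location) are part of the output contract so recovery tests never
reach into the generator's internals.

Default conditions mirror the headline study layout: 455 populations of
268 species (135 birds, 89 mammals, 44 herptiles) over the 14 populated
subsets, spans inside 1970–2014 (first year uniform on 1970–2000, span at
least 8 years so every index year is populated and most series take the
GAM path), μ = log10 0.983, σ_obs = 0.05, 20 % missingness.  The
terrestrial-style variant sets μ = log10 0.988.  The mixed-model power
scenario generates responses directly at the population level (n = 500,
100 locations, 20 % exploited, δ = −0.02, location SD 0.02, residual SD
0.05) — prevalence and noise chosen once as realistic for rate-of-change
data of this kind.  The influence fixture gives the bulk of genera a real
common predictor effect and appends one erratically declining genus whose
huge residual spread masks the effect — the situation where excluding that
genus (and only that genus) flips the significance verdict.

What passing these tests shows: the pipeline is unbiased and internally
consistent under its own assumptions (exponential trends, independent
lognormal noise, missingness at random, independent species).  What it does
not show: robustness to serially correlated observation error, density
dependence, catastrophic crashes, non-random monitoring effort, or shared
trends between species — all present in real monitoring data.

## Numerical choices and limitations

- log base 10 throughout; rate cap ±1; GCV grid 10⁻⁸…10⁸ (41 points) with
  a 10⁻¹⁰ ridge for numerical safety.
- Replicate sizes in tests (10 seeds for index recovery, 200 replicates
  for mixed-model power/size, 50 runs × B = 200 for bootstrap coverage)
  were sized to keep Monte-Carlo error well inside the asserted tolerances.
- Bootstrap unit is the species; population-level resampling would
  understate uncertainty for multi-population species.
- The index cannot distinguish composition drift from status change — use
  the turnover diagnostics alongside it.
- Multivariate follow-up models are out of scope (the univariate screen is
  the deliverable); spatial and phylogenetic autocorrelation are not
  modelled.
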