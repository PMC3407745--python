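# Methods

`citylur` implements a complete exposure-assessment-and-mortality analysis for
a traffic pollutant (NO₂, µg/m³) measured with passive samplers in two
campaigns years apart: land use regression (LUR) models per campaign, their
diagnostics and cross-period transportability, exposure assignment to a
cohort, and Cox proportional-hazards regression of natural mortality on the
assigned exposure. Because no real monitoring or cohort data ship with the
package, every stage runs against a synthetic city whose ground truth is
known, so each estimate can be checked against the quantity that generated it.

## The synthetic city

The study area is a square of side 24 km (planar metres; no geodesy). The
road network is radial: spokes from the centre whose traffic counts decay
outward, two urban ring roads, and an orbital motorway at the periphery
carrying 60,000–90,000 vehicles/day. Only roads with counts ≥ 4,000
vehicles/day are represented at all (minor streets carry no count data), and
a road is *high traffic* iff its count strictly exceeds 10,000 vehicles/day.
Census blocks form a warped grid — cells are smaller near the centre, as in
an old urban core — and carry residents (Poisson, mean decaying exponentially
from the centre with a 6 km scale), area, terrain altitude (a smooth
deterministic field with hills on two sides of the city plus a gentle
latitudinal trend), and a green-adjacency indicator whose probability rises
toward the suburbs.

## The latent pollution surface

Log concentration is linear in the land-use predictors plus a spatially
correlated residual:

    ln NO₂(s) = β₀ + Σⱼ βⱼ xⱼ(s) + η(s)

with defaults β₀ = 4.36 and nonzero coefficients on distance to centre
(−6.5·10⁻⁵ per m), altitude (−2.5·10⁻³ per m), the x coordinate (+8·10⁻⁶ per
m, a stand-in for an orography/wind gradient), traffic density in the 150 m
buffer (+8·10⁻⁴ per vehicles·m/m²), and distance to the nearest high-traffic
road (−1·10⁻⁴ per m). These give a site-level geometric mean near 45 µg/m³, a
between-site SD of roughly 10–14 µg/m³, background-vs-traffic contrasts of
20–40%, and land-use predictors explaining ~70–80% of log variance — the
regime a city-scale LUR typically operates in. η is a Gaussian field with
exponential covariance (SD 0.12 on the log scale, range 3 km), simulated
exactly by Cholesky factorisation on a coarse grid whose spacing tracks the
correlation range, then bilinearly interpolated. The field is *shared*
between campaigns: with zero drift and noiseless samplers, campaign 2 equals
campaign 1 exactly, which anchors all the transportability contracts.

Campaign 2 applies a drift of −0.075 on the log scale plus +5·10⁻⁴ × traffic
density, so concentrations decline everywhere but decline less at
traffic-dense locations, preserving rank order between campaigns.

## Campaigns, samplers, calibration

Each campaign deploys samplers for three one-week periods (seasonal offsets
+3/−1/−2 µg/m³); a site's annual value is the arithmetic mean of its periods,
and sites missing any period are dropped (the default missingness rate 3/70
makes roughly three of seventy sites incomplete). Devices respond affinely:
reading = gain·(truth + period effect + noise) + offset, floored at 1 µg/m³.
Campaign 1 uses a distorted device (gain 1/0.68, offset −13.53/0.68 µg/m³) —
the exact inverse of the calibration line `reference = 0.68·distorted + 13.53`
— and campaign 2 the reference device; both have measurement noise SD
4 µg/m³ per period. The calibration module regresses reference on distorted
readings at 27 co-located sites (plain OLS, the direction matching how such
corrections are applied in practice) and maps all campaign-1 records onto the
reference scale before annual means are formed. Agreement is summarised by
Bland–Altman statistics (mean difference, SD with the n−1 denominator, limits
mean ± 1.96·SD).

## Predictors

All predictors are computed from scene geometry at arbitrary points: planar
coordinates, distance to centre, altitude, block size/residents/inverse
population density (m² per person), green adjacency, and three traffic
metrics in a single 150 m buffer — metres of high-traffic road (segment ∩
disc length computed analytically by clipping the segment parameter to the
circle; a dense polygonal buffer serves as the independent oracle in tests),
traffic density (Σ count × in-buffer length over *all* counted roads, divided
by the buffer area — the definition is ambiguous between all counted roads
and the high-traffic subset; the all-roads reading is used and flagged here),
and distance to the nearest high-traffic road (an error, not zero, when no
such road exists). Block membership ties on shared boundaries resolve to the
smallest block id.

## LUR fitting

The response is ln(annual mean). Selection is manual-style backward
elimination from the full candidate set with p-to-remove 0.20, plus two
domain rules, applied in this order each iteration:

1. **Sign rule** — a sign-constrained predictor whose current coefficient
   contradicts its expected direction is removed first, worst violator
   (largest p) first. Expected directions: positive for buffer road length,
   traffic density and block residents; negative for distance to centre,
   distance to high-traffic road, altitude, block size, inverse population
   density and green adjacency; coordinates unconstrained. The rule is
   applied iteratively to the multivariable fit by default; a `prescreen`
   mode applies it once to univariate slopes instead.
2. **p rule with coordinate pairing** — remove the largest-p predictor above
   0.20, except that a coordinate whose partner is retained on merit
   (partner p ≤ 0.20) cannot be removed; if one coordinate earns its place,
   both stay.

Ties in p break by removing the predictor later in the canonical schema
ordering. Constant columns are dropped up front. An empty endpoint returns an
intercept-only model with a warning. Predictions back-transform by naive
exponentiation; a Duan smearing factor is stored on the model but off by
default, since the generating surface is exactly log-linear and the
acceptance contracts are written on the naive back-transform.

## Validation

* **LOOCV** refits the coefficients of the *fixed* selected predictor set
  with each site held out (re-running the selection per fold is available
  behind a flag but is not the default, matching standard LUR practice), and
  reports R²/adjusted R² of measured-on-predicted and RMSE on the
  concentration scale.
* **VIF** per selected predictor, 1/(1−R²ₖ); perfect collinearity reports
  `inf` rather than raising. **Cook's distance** uses the classical
  closed form; a numerically perfect fit returns zeros (the 0/0 guard), and
  sites above a 0.3 threshold are flagged.
* **Moran's I** of residuals uses inverse-distance, row-standardised weights
  by default (k-nearest and distance-band schemes provided), with a
  two-sided permutation p-value (count+1)/(n_perm+1) around the
  exchangeability expectation −1/(n−1); 999 permutations and an explicit
  seed by default, with a normal-approximation analytic p as an option.
* **Cross-period prediction** applies one campaign's model to the other
  campaign's sites and reports Pearson r overall and by site type.

## Cohort and survival

Addresses are drawn with probability proportional to block population,
uniformly within the block. The block-level socioeconomic category
(1 = most deprived … 5 = most affluent) is the quintile of a latent score
mixing the block's true NO₂ (weight 0.6 by default) with independent noise —
affluent central areas are more polluted, so socioeconomic position confounds
positively. All other covariates (age band, gender, marital status, place of
birth, education, occupation) are drawn independently of address. Survival
times are exponential with log hazard linear in true NO₂ (default
ln(1.06) per 10 µg/m³) plus category effects, with administrative censoring
at 5.2 years and a baseline rate targeting ~6.5% deaths. The default cohort
size is 20,000 — large enough for stable hazard-ratio estimation while
keeping simulation studies (100-replicate coverage runs) tractable; the
qualitative structure does not depend on this choice.

The Cox model is fit by a self-contained Newton–Raphson maximiser of the log
partial likelihood with the Efron tie correction by default (Breslow
optional), convergence at max|score| < 10⁻⁸ or relative log-likelihood change
< 10⁻¹⁰, step-halving for safety, and explicit errors for monotone
likelihood (diverging or flat estimates), constant exposure columns, and
zero events. Covariance is the inverse observed information; CIs are Wald on
the log scale. Exposure codings: linear (per-10 and per-IQR hazard ratios via
HR(δ) = exp(βδ), with δ = Q75−Q25 of the analysis population in IQR mode),
empirical quintiles (ties to the lower group), and four fixed classes with
left-open/right-closed bounds (−∞,35], (35,45], (45,50], (50,∞). Trend tests
across ordered categories refit the model with a single ordinal score and
report its Wald p. Time scale is time-on-study with age adjusted as a
covariate; reference levels are the lowest exposure group and each
covariate's most frequent level. An independent survival package is used
only as a cross-check in the test suite, never in the implementation.

Descriptive layers: stratified exposure summaries (linear-interpolation
quantiles), Cuzick's rank-based trend test across ordered groups (midranks
with a tie-corrected variance), and Welch's t-test between genders.

## What the generator does and does not emulate

It reproduces the *structure* of a two-campaign LUR study — log-linear
surface, spatially correlated residual, affine device differences, drift with
preserved rank order, confounded socioeconomic gradient, rare-event cohort —
with sizes scaled to what a single CPU simulates comfortably (70/78 sites,
27 pairs, 20,000 subjects). It does not emulate real geography, seasonal
meteorology beyond constant period offsets, device error that varies with
weather, residential mobility, or cause-of-death coding. Passing tests
therefore demonstrate the estimators' correctness and calibration under the
stated model, not the accuracy of any particular real-world exposure map.

## Numerical choices and limitations

OLS uses an explicit intercept, two-sided t tests on n−k degrees of freedom,
and `RMSE = √(SSE/(n−k))` on the log scale. Concentrations are floored at
1 µg/m³ before logging. The Gaussian field grid is capped (spacing ≥
range/2.5) so Cholesky stays cheap; fields evaluated below the grid scale are
interpolated, slightly smoothing short-range correlation. The stepwise
endpoint is order-dependent by construction (that is what a manual backward
procedure is); the exhaustive-subset comparison lives only in tests. Hazard
ratio non-collapsibility means unadjusted fits attenuate toward the null even
without confounding — simulation checks therefore always adjust for the
covariates whose effects were generated.
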