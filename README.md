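# citylur

Land use regression (LUR) exposure assessment and cohort mortality analysis,
exercised end to end on a synthetic city with known ground truth.

LUR is the workhorse of air-pollution epidemiology: regress measured
pollutant concentrations (here NO₂, µg/m³, from week-long passive-sampler
deployments) on the geography around each monitoring site — traffic within a
buffer, distance to major roads, population density, altitude, position —
then predict concentrations at every cohort address and relate the assigned
exposure to mortality. A recurring methodological question is whether a model
built from one monitoring campaign can stand in for exposure years earlier or
later. `citylur` implements the full chain needed to study that question —
two campaigns years apart, device calibration, model building and
diagnostics, cross-period transport, exposure assignment, and Cox
proportional-hazards mortality models — as a tested Python library, with a
synthetic-city generator supplying data whose generating parameters are
known, so every estimator can be validated against the truth that produced
its input.

It is written for biostatisticians and exposure-assessment researchers who
want a transparent, fully checkable implementation of this pipeline.

## The model

Site annual means are the arithmetic mean of three one-week deployments
(sites missing a period are dropped). The exposure model is log-linear,

  ln NO₂(s) = β₀ + Σⱼ βⱼ xⱼ(s) + ε(s),

fitted by manual-style backward elimination (p-to-remove 0.20) with two
domain rules: predictors whose slope contradicts its expected direction are
removed first (sign constraint), and the planar coordinates enter or leave as
a pair — if one is selected on merit, the other is kept regardless of its
p-value. Diagnostics: leave-one-out cross-validation (R², adjusted R², RMSE
on the concentration scale), variance inflation factors, Cook's distance, and
Moran's I of residuals with a permutation test. Two sampler types are aligned
by OLS on co-located pairs (the synthetic distorted device inverts
`reference = 0.68·distorted + 13.53`), with Bland–Altman agreement.

Mortality follows a Cox proportional-hazards model fitted by a
self-contained Newton–Raphson maximiser of the partial likelihood (Efron tie
correction by default), with exposure coded linearly (HR per 10 µg/m³ and per
interquartile range, HR(δ) = exp(βδ)), as empirical quintiles, or as four
fixed classes (≤35, 35–45, 45–50, >50 µg/m³), adjusted for age band, gender,
marital status, place of birth, education, occupation and an area
socioeconomic index that the generator deliberately confounds with exposure.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the study stage by stage (each is
a thin driver over the library and writes its artifacts under the chosen
output directory):

```bash
python analysis/01_simulate.py          --seed 1 --out results/run
python analysis/03_calibrate_samplers.py --seed 1 --out results/run
python analysis/04_fit_lur_models.py     --seed 1 --out results/run
python analysis/06_compare_periods.py    --seed 1 --out results/run
python analysis/07_fit_survival_models.py --seed 1 --out results/run
```

At seed 1 the calibration stage prints

```
calibration on 27 co-located pairs: reference = 0.681 * distorted + 14.00  (R^2 = 0.920)
generating distortion corresponds to slope 0.680, intercept 13.53
```

— the fitted line recovers the device distortion the generator applied. The
model stage reports, for campaign 1,

```
model1 (campaign 1, 66 sites): adjusted R^2 = 0.911, log-scale RMSE = 0.093
  dist_centre            -0.0000573   p = 0.000
  altitude               -0.0032142   p = 0.000
  traffic_density_150     0.0011087   p = 0.000
  dist_hi_road           -0.0001396   p = 0.000
  ...
```

with every generating predictor retained at roughly its true coefficient
(truth: dist_centre −6.5·10⁻⁵, altitude −2.5·10⁻³, traffic density
+8·10⁻⁴, distance to high-traffic road −1·10⁻⁴). The period comparison
prints

```
A  measured campaign 1 vs 2:        r = 0.96
D  model 1 vs model 2 at addresses: r = 0.98
model smoothing: address-level agreement exceeds site-level agreement
```

— assigned exposures agree more strongly between models than raw
measurements do between campaigns, because prediction strips the measurement
noise. The survival stage, on 20,000 subjects with 1,657 deaths generated at
a true HR of 1.06 per 10 µg/m³, prints

```
per 10 ug/m3:  HR 1.03 (0.99-1.07)
per IQR (19.4 ug/m3):  HR 1.05 (0.97-1.14)
```

— the confidence interval covers the generating truth (the point estimate
moves with the seed; CI coverage is verified at the nominal rate in the test
suite).

The same pipeline is available as a CLI (`citylur run --seed 1 --out results/run`,
with per-stage subcommands) and as one call,
`citylur.run_pipeline(PipelineConfig(seed=1), "results/run")`.

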