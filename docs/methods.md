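# Methods

This note documents the models and procedures implemented in `phenoclim`,
their assumptions, the parameters that matter, and the design decisions taken
where the problem was genuinely open. No empirical claim is made here that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Weather records

An environment's record is an hourly series of air temperature (°C), relative
humidity (%) and optionally global radiation (W m⁻²) on local civil clock
time. Chamber programs are defined on clock hours, so no daylight-saving or
astronomical correction is applied; day boundaries are midnight, and the
integer `experiment_day` (day 0 = first day) is the cross-environment
alignment axis, because chamber experiments map their dates *relatively* onto
the template season they simulate.

Hours missing from a raw file are flagged at read time and kept as a gap list.
`impute_gaps` fills every channel by linear interpolation inside the series;
gaps at a boundary are not imputable, and gaps longer than a configurable cap
(default 24 h) raise rather than fill — long sensor outages should be handled
deliberately, not silently. The gap list survives imputation so that
comparison metrics can exclude imputed hours (the default).

## 2. Regime compilation

Both modes build weeks from three model day types:

* **daylight mean** — the ranking statistic for sunny/cloudy selection is the
  mean temperature over programmed daylight hours (sunrise ≤ h < sunset). A
  "lowest/highest day temperature profile" criterion needs a scalar summary;
  the daylight mean is the natural one and ties break deterministically
  toward the earlier weekday (with a warning).
* **averaged mode** — per calendar week, the seven *median days* are hour-wise
  medians per weekday slot across the template years (a composite, not a
  selected real day; the selected-real-day reading is the main alternative and
  would be a one-line change in `median_weekday_profiles`). Cloudy/sunny are
  the extreme median days, the normal day is the hour-wise mean of all seven.
  The weekly sequence is fixed: Monday-first
  `sunny, normal, normal, cloudy, normal, sunny, cloudy`
  (3 normal / 2 sunny / 2 cloudy), identical in every week.
* **single-season mode** — per week of a single template year, the normal day
  is the hour-wise mean of the week's seven real days; sunny/cloudy are the
  individual real days with extreme daylight means. Each real day is
  classified sunny/cloudy/normal against the weekly daylight mean ± a band
  (default ±1.0 °C — the classification criterion needs a threshold for
  mid-range days and the sources of such rules give none; it is configurable).
  The emitted sequence preserves the classification counts with same-type
  days placed in maximal consecutive runs, ordered by first occurrence —
  pressure systems persist for more than a day, so runs beat random placement.
  An all-one-type week is allowed and noted.

The auxiliary schedules are programmed, not measured:

* **humidity** — 90 % RH at night; linear ramp from sunrise to a plateau of
  40 % (normal/sunny) or 50 % (cloudy) held for the central 5 h of the
  photoperiod; linear ramp back to 90 % at sunset.
* **light** — per-day-type base intensity (940 / 961 / 319 µmol m⁻² s⁻¹ for
  normal / sunny / cloudy) inside the photoperiod, zero outside; a centrally
  placed "cloud cover" window of 5 / 2 / 8 h in which the intensity follows a
  sinusoid dipping to ⅓ of the base with a 2 h period. Window placement,
  modulation depth and period are artifact choices (the fluctuation is
  specified as sinusoidal but not parameterized anywhere authoritative) and
  are configurable.
* **wind** — night oscillation between 10 and 20 % of maximal rotation,
  morning/afternoon linear ramps between 30 and 50 %, constant 50 % for the
  central 5 h, direction flag alternating every 2 h.
* **day length** — sunrise −10 min and sunset +10 min per week up to a
  reversal week (default week 7, ≈ the summer solstice for a season starting
  in early May), mirrored afterwards. Sunrise/sunset come from this rule and
  a configurable base (06:00–20:00), not from an astronomical model, matching
  programmed rather than astronomical photoperiods.

Compiled temperature setpoints are clamped to the facility bounds
(0–47.5 °C) and clamp events are counted in the regime metadata.

## 3. Environment similarity

Saturation vapor pressure uses the Arden Buck formula over water with
constants a_w = 6.1121 hPa, b_w = 18.678, c_w = 257.14 °C, d_w = 234.5 °C;
VPD = e_s(T)·(1 − RH/100), reported in kPa. At 0 °C the exponent vanishes and
e_s = a_w exactly — a useful analytic anchor.

Thermal time accrues per hour as (1/24)·f(T)/f(T₂₀) with the maize response
f(T) = T·e^{−ΔH_A/(RT)} / (1 + [e^{−ΔH_A/(RT₂₀)}]^{α(1−T/T_o)}),
−ΔH_A = −73 900 J mol⁻¹, R = 8.314 J mol⁻¹ K⁻¹, T₂₀ = 293 K, T_o = 306.4 K,
α = 3.5. Temperatures are converted as K = °C + 273.15, but T₂₀ is used as
printed (293 K, i.e. 19.85 °C — not 293.15 K); the increment equals 1/24
exactly at 293 K and has its interior maximum below T_o. The cumulative sum
requires a gap-free series (impute first); per-day totals give the
thermal-time day profiles used for day-scale comparisons.

`compare_environments` pairs hour k of one environment with hour k of the
other, counted from each season's start, truncating to the shorter record;
for the `tt_day` channel the unit is the experiment day. It reports Pearson
r, R² = r², the two-sided p from the t-transform of r, and RMSE over the same
aligned values, excluding imputed hours by default (whether published
correlations excluded imputed hours is unstated; the flag exists for both
readings). A minimum overlap of 48 h (2 days for `tt_day`) is enforced.

## 4. Growth and development models

**BLUEs.** For each measurement date and environment, a linear mixed model is
fit by REML with genotype fixed and the design's positional terms random.
Three design registries cover the container trials (replicate, container
row/column, plant position, and replicate interactions), the glasshouse
(replicate, pot row), and the field (replicate, plot position, and their
interaction). Variance components may sit at the zero boundary; they are
reported, and a factor whose levels map 1:1 onto genotypes raises a design
error (it would be confounded). Estimation uses `statsmodels` MixedLM with
crossed variance components over a single technical group; the derivative-
free Powell search is used because boundary components make the REML surface
non-smooth and defeat the gradient-based optimizers. On balanced data with
zero positional variance the BLUEs reduce to genotype means.

**Logistic growth model.** The population model for a trait over time is the
3-parameter logistic y(x) = Asym/(1 + e^{(xmid−x)/scal}) (or the 4-parameter
variant A + (B−A)/(1 + e^{(xmid−x)/scal}) for thermal-time axes), with
environment-level fixed parameters and genotype-level random deviations for
the asymptote and xmid; scal is shared across genotypes (its genotype
variance is consistently negligible, and any random term whose estimated sd
falls below 10⁻⁶ of the response scale is removed and the model refit, with a
log entry).

Estimation is a precision-weighted two-stage procedure rather than a joint
nonlinear mixed-model maximization with an ARMA residual covariance:

1. per genotype × environment, a least-squares logistic fit with
   self-starting values (Asym₀ = 1.05·max y; xmid₀ = first crossing of
   Asym₀/2 by linear interpolation; scal₀ = (t₇₅ − t₂₅)/2.2) yields parameter
   estimates and their sampling variances;
2. per parameter, a random-effects meta-model
   y_ge = β_env + u_g + e_ge, u_g ~ N(0, σ²_g), e_ge ~ N(0, v_ge + σ²),
   is fit by REML (profiled fixed effects, Nelder–Mead over the two variance
   parameters), giving environment fixed effects with their covariance and
   genotype BLUPs.

The rationale: the inferential targets are the environment parameters and the
genotype deviations, both recoverable two-stage; serial correlation of the
residuals is *reported* (Ljung–Box over 10 lags on the stage-1 residuals, the
order choice (2,2) living in the generator, not in an automated search)
instead of being folded into the likelihood. The test suite verifies Asym
recovery within 3 % and xmid within 2 DAS (median over 20 seeds) at the
default design scale under ARMA(2,2) residuals. Marginal and conditional
determination coefficients follow the standard fixed vs fixed+random variance
partition per stage-2 model; the conditional coefficient is ≥ the marginal by
construction.

**Derivatives, predictions, clustering.** Growth speed is the analytic
derivative scaled to percent of the asymptote per time unit (25/scal at
xmid). Genotype-specific curves (fixed + random effects) are evaluated at a
common reference time (e.g. the mean field inflection) to build the
genotype × environment matrix, whose rows are standardized (mean 0, sd 1,
ddof 1) before complete-linkage clustering of the environments on Manhattan
distances; constant rows are dropped with a warning and ties resolve by
scipy's deterministic ordering.

**Tasseling.** Population tassel percentages per environment × day are fit by
per-environment least-squares logistic curves (time and cultivation are the
fixed factors); residuals and fitted values each go into a two-way ANOVA with
factors time and cultivation. Environments with fewer than 4 time points are
excluded; decreasing percentages are logged, not fatal; a saturated design
(single environment) skips the ANOVA with a log entry.

**Repeatability.** Across environments, the square-root-transformed trait is
fit by REML with experiment and measurement date fixed and genotype,
genotype × experiment, genotype × date random;
R_genotype = σ²_genotype/(σ²_genotype + σ²_ε). Dates are nested within
experiments, which aliases the experiment factor; the implementation detects
nesting and fits the equivalent full-rank fixed model (the nested date factor
spans the experiment contrasts).

**Variance decomposition.** In the homogeneity trial, the square-root trait
is fit with genotype fixed and preculture, column, row, replicate and soil
random. Agreement-repeatability shares: the genotype share is the variance of
the fixed predictions; each factor contributes its variance component; all
over the total including σ²_ε, so shares are non-negative and sum to one.
Percentile confidence intervals come from a parametric bootstrap (simulate
from the fitted components, refit; default 1000 cycles, 200 in the test
suite for runtime).

**Yield components.** BLUPs per environment come from the same design models
with genotype random (computed explicitly as σ²_g Z'V⁻¹(y − μ̂); full
shrinkage to the grand mean at σ²_g = 0). Environment estimated means come
from a model with cultivation fixed and genotype random; all-pairs contrasts
use the studentized-range distribution with df = n − n_env − n_genotypes + 1
(a Satterthwaite-style residual count, recorded in the result log).

**Parameter contrasts.** Pairwise environment differences per logistic
parameter use the stage-2 covariance; p-values are normal-based (two-stage
large-sample) with Bonferroni correction over the pairs within a parameter
family, and the confidence intervals are at the 1 − α/m level.

## 5. Synthetic data

The generators produce the statistical structure the pipeline assumes — not a
statistical match to any real site's climate or any real population.

* **Weather** (135-day season, hourly): daily means rising from 13 °C to a
  20 °C midsummer peak on a half-sine; an 8 °C diurnal cosine peaking at
  14:00; an AR(1) day-scale anomaly (φ = 0.7, stationary sd 2.5 °C) creating
  persistent sunny/cloudy spells; 0.5 °C hourly noise. RH is a night-high
  diurnal cycle anti-coupled to the day anomaly (−3 % per °C), clipped to
  [5, 100]; radiation is a clear-sky half-sine scaled by an anomaly-linked
  cloudiness factor, zero at night. What it does **not** emulate: weather
  fronts moving through within a day, heat waves beyond AR(1) persistence,
  radiation–temperature lags, or any site's actual covariance structure — so
  passing tests demonstrate algorithmic correctness and the averaged-vs-
  single-season fidelity ordering, not climatological realism.
* **Phenotypes** (11 genotypes × 7 environments, twice-weekly sampling on
  days ≡ 0 and 3 mod 7): genotype-specific logistic curves with environment
  parameters defaulting to four field-like seasons (Asym ≈ 195–220 cm,
  xmid ≈ 66.5–69 DAS), a static-glasshouse-like environment (xmid 38) and an
  averaged-regime-like environment (xmid 48) — the qualitative contrast of
  field-like vs accelerated artificial environments, with a single-season-
  chamber environment matching the field inflection. Genotype random effects
  (sd 18 cm on Asym, 2.5 DAS on xmid), small design-factor effects, and
  ARMA(2,2) residuals (ar 0.4, 0.2; ma 0.3, 0.1; 100-step burn-in; marginal
  sd 5 cm scaled down early in the season, where real measurement noise is
  smaller). One root seed spawns child streams in the order effects →
  residuals → design, so each is independently re-drawable.
* **Tasseling**: per-plant onset is a logistic quantile draw around the
  environment median; percentages are non-decreasing by construction.
* **Homogeneity trial**: 55 containers (5 × 11 grid), soil groups 25 reused /
  25 top-exchanged / 5 renewed, two genotypes randomized to container sides,
  preculture labels per container. Components are planted on the square-root
  scale (the scale the decomposition model uses) with default shares 0.70
  genotype, 0.05 row, 0.25 residual on a total variance of 4 — small against
  the mean so the non-negativity floor never truncates.
* **Repeatability table**: effects planted directly on the square-root scale
  with σ²_g = σ²_ε = 1 (R = 0.5); 5 experiments × 8 dates × 2 replicates by
  default, a scale at which one REML fit stays light while the genotype
  variance is still well identified.

## 6. Numerical choices and limitations

* Stage-1 logistic fits are bounded (scal > 0, Asym > 0, xmid within one
  season-span of the data); non-convergent groups are excluded with a log
  entry rather than failing the population fit.
* REML surfaces with boundary variance components are handled by
  derivative-free optimizers (Powell in MixedLM, Nelder–Mead in the stage-2
  meta-model).
* Variance shares are reported to machine precision; displayed p-value
  conventions (e.g. thresholds) are formatting concerns left to callers.
* CSV round-trips are bit-identical (shortest-repr floats on write,
  `float_precision="round_trip"` on read).
* The two-stage logistic estimator is not a joint-likelihood nonlinear mixed
  model: it will not reproduce another implementation's likelihood values or
  standard errors exactly, and with very few time points per group the
  stage-1 variances (hence stage-2 weights) degrade. Residual ARMA structure
  is diagnosed, not modeled.
* The pipeline's default per-date genotype estimates are arithmetic means
  (identical to the mixed-model BLUEs on balanced synthetic data); the full
  per-date REML path is available via `blue_method="mixed"`.
* Regime fidelity comparisons treat compiled setpoints as achieved
  conditions; actuator dynamics, spectral composition, CO₂ and soil
  temperature are out of scope.
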