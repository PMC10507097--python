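# phenoclim

Controlled-environment plant cultivation facilities can be programmed to
*simulate* the weather of a real field season. `phenoclim` implements the
computational core of that workflow for plant phenomics: it compiles hourly
field-weather records into week-by-week chamber climate programs, quantifies
how closely a programmed environment tracks the season it emulates, and
analyzes the plant growth and development time series such experiments
produce. It is aimed at researchers running (or benchmarking) dynamic
climate-simulation chambers against field trials, and ships a seeded
synthetic-data module so that every stage is testable without any external
data.

## What it computes

**Climate regimes.** Two compilation modes turn template seasons into chamber
programs built from three model day types (normal / sunny / cloudy, ranked by
daylight-mean temperature):

* *averaged* — each calendar week uses hour-wise median weekday profiles
  across several template years; every week runs a fixed sequence of
  3 normal, 2 sunny and 2 cloudy days;
* *single-season* — each week copies one template year: day-type frequencies
  follow a ±1 °C classification band around the weekly daylight mean, and
  same-type days are emitted consecutively, mirroring persistent weather
  fronts.

Relative humidity, light, wind, and day length are programmed schedules
(90 % night RH ramping to a 40 %/50 % midday plateau over the central 5 h;
sinusoidal "cloud cover" light windows at 940/961/319 µmol m⁻² s⁻¹; wind
bands with 2-hourly direction switches; ±10 min of day length per week with a
midsummer reversal), with temperature setpoints clamped to the facility range
0–47.5 °C.

**Environment similarity.** Pearson *r*, *R²*, two-sided *p* and RMSE between
environments aligned by experiment-relative hour, on three channels: air
temperature; vapor pressure deficit from the Arden Buck saturation formula

&nbsp;&nbsp;&nbsp;&nbsp;e_s(T) = 6.1121 · exp((18.678 − T/234.5) · T / (257.14 + T)) hPa,&nbsp;&nbsp;VPD = e_s(T) · (1 − RH/100);

and cumulative thermal time, an Arrhenius-type maize temperature response
normalized to a constant 293 K reference (one thermal-time day = one day at
that reference temperature):

&nbsp;&nbsp;&nbsp;&nbsp;tt_n = tt_{n−1} + (1/24) · f(T)/f(T₂₀),&nbsp;&nbsp;
f(T) = T·e^{−ΔH_A/RT} / (1 + [e^{−ΔH_A/RT₂₀}]^{α(1−T/T_o)}),

with −ΔH_A = −73 900 J mol⁻¹, T₂₀ = 293 K, T_o = 306.4 K, α = 3.5.

**Growth and development statistics.** Per-date genotype BLUEs from REML
linear mixed models matching the trial design; a three- or four-parameter
logistic growth model y(x) = Asym / (1 + e^{(xmid − x)/scal}) with
environment fixed parameters and genotype random deviations (precision-
weighted two-stage estimation, Ljung–Box autocorrelation diagnostics);
derivative/growth-speed curves; Manhattan-distance complete-linkage
clustering of the genotype × environment height matrix at a common inflection
time; a fixed-effect logistic model of population tasseling percentages;
genotype repeatability R = σ²_g/(σ²_g + σ²_ε) with marginal/conditional
determination coefficients; positional variance decomposition with
parametric-bootstrap intervals; and yield-component BLUPs with Tukey-adjusted
environment contrasts.

## Worked example

```python
import phenoclim as pc

years = pc.generate_weather(pc.WeatherGenConfig(n_years=3), seed=7)
avg = pc.compile_season_regime("averaged", years=years)
sim = pc.compile_season_regime("single_season", template_year=years[0])
for label, regime in [("averaged", avg), ("single-season", sim)]:
    cmp_ = pc.compare_environments(pc.regime_to_series(regime, label), years[0])
    print(f"{label:>14} vs template: r = {cmp_.pearson_r:.2f}, "
          f"RMSE = {cmp_.rmse:.2f} °C (n = {cmp_.n} h)")

table, truth = pc.generate_phenotypes(seed=7)
blues = (table.groupby(["environment", "genotype", "das"])["plant_height"]
              .mean().rename("value").reset_index())
fit = pc.fit_logistic_population(blues)
for env in fit.environments:
    print(f"{env:>12}: Asym = {fit.fixed['Asym'][env]:6.1f} cm, "
          f"xmid = {fit.fixed['xmid'][env]:5.1f} DAS")
clust = pc.cluster_environments(pc.height_matrix_at(fit, 68.0))
print("cluster order:", " | ".join(clust.leaf_order))
```

prints

```
      averaged vs template: r = 0.81, RMSE = 2.65 °C (n = 3192 h)
 single-season vs template: r = 0.88, RMSE = 2.08 °C (n = 3192 h)
 chamber_avg: Asym =  247.3 cm, xmid =  47.8 DAS
 chamber_sim: Asym =  223.9 cm, xmid =  68.1 DAS
  field_2016: Asym =  220.8 cm, xmid =  68.0 DAS
  field_2017: Asym =  204.2 cm, xmid =  67.0 DAS
  field_2018: Asym =  208.3 cm, xmid =  69.4 DAS
  field_2019: Asym =  195.7 cm, xmid =  66.7 DAS
  glasshouse: Asym =  266.4 cm, xmid =  38.0 DAS
cluster order: field_2018 | chamber_sim | field_2016 | field_2017 | field_2019 | chamber_avg | glasshouse
```

The single-season program tracks its template year more closely than the
averaged one (r = 0.88 vs 0.81, lower RMSE); the fitted inflection points
(xmid, the time of peak growth rate) recover the planted contrast — field-like
environments and the single-season chamber run inflect around 68 days after
sowing, the averaged chamber regime ~20 days earlier and the static
glasshouse ~30 days earlier — and the clustering at 68 DAS groups the
single-season simulation with the field seasons, away from the averaged
regime and the glasshouse.

## Command line

```
phenoclim simulate --what weather|phenotypes|tassel|homogeneity --seed N --out DIR
phenoclim build-regime --mode averaged|single --years a.csv --years b.csv ... --out regime.csv
phenoclim env-metrics --a env1.csv --b env2.csv --channel temperature|vpd|tt_day --out cmp.json
phenoclim fit-growth --phenotypes table.csv --trait plant_height --nparams 3 --out fit.json
phenoclim decompose-variance --phenotypes hom.csv --n-boot 1000 --out dec.json
phenoclim report --seed N --out DIR        # full synthetic end-to-end bundle
```

Weather CSVs use the header
`timestamp,temperature,relative_humidity,global_radiation` with ISO-8601
timestamps; missing values are empty fields, flagged as gaps at read time and
linearly imputed on request (24 h cap).

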