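"""Seeded synthetic-data generators for weather and phenotype fixtures.

The generators emulate the statistical structure the pipeline assumes so every
stage is testable without external data:

* multi-year Central-European May–September hourly weather — a seasonal mean
  trend, a diurnal cycle, an AR(1) day-scale anomaly process (creating sunny
  and cloudy days), hourly noise, relative humidity anti-coupled to the
  temperature anomaly, and a clear-sky radiation sinusoid scaled by
  cloudiness;
* phenotype time series following genotype-specific logistic growth with
  environment-level parameter shifts, genotype random effects, design-factor
  effects, and ARMA-autocorrelated residuals sampled twice weekly (Mondays and
  Thursdays);
* population tasseling percentages from per-plant logistic onset draws;
* a spatial-homogeneity trial (2 genotypes × 55 containers × 2 sides with
  soil-treatment and preculture labels) with planted variance components.

Every generator is a pure function of (config, seed): one root seed spawns
per-stream child seeds (weather → effects → residuals, in that order), so
repeated invocation is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from statsmodels.tsa.arima_process import ArmaProcess

from .weather import HourlyWeatherSeries

# -- weather -------------------------------------------------------------------


@dataclass
class WeatherGenConfig:
    """Synthetic season structure.

    Defaults emulate a 135-day May–September season at a temperate site: daily
    means rising from ~13 °C to a ~20 °C midsummer peak, an 8 °C diurnal
    amplitude peaking at 14:00, persistent (AR(1) φ = 0.7) day-scale anomalies
    with 2.5 °C stationary spread, and 0.5 °C hourly sensor-scale noise.
    """

    n_years: int = 3
    season_days: int = 135
    start_mean_c: float = 13.0
    peak_mean_c: float = 20.0
    diurnal_amplitude_c: float = 8.0
    diurnal_peak_hour: float = 14.0
    anomaly_ar1: float = 0.7
    anomaly_sd: float = 2.5
    hourly_noise_sd: float = 0.5
    rh_base: float = 70.0
    rh_diurnal_amplitude: float = 15.0
    rh_coupling_slope: float = 3.0  # % RH per °C of day anomaly
    radiation_peak_wm2: float = 750.0
    sunrise: float = 6.0
    sunset: float = 20.0
    start_dates: tuple = ("2016-05-02", "2017-05-02", "2018-05-02", "2019-05-02")


def generate_weather(
    config: WeatherGenConfig | None = None, seed: int = 0
) -> list[HourlyWeatherSeries]:
    cfg = config or WeatherGenConfig()
    streams = np.random.SeedSequence(seed).spawn(cfg.n_years)
    out = []
    d = np.arange(cfg.season_days)
    h = np.arange(24.0)
    seasonal = cfg.start_mean_c + (cfg.peak_mean_c - cfg.start_mean_c) * np.sin(
        np.pi * d / cfg.season_days
    )
    diurnal = 0.5 * cfg.diurnal_amplitude_c * np.cos(
        2 * np.pi * (h - cfg.diurnal_peak_hour) / 24.0
    )
    daylight = np.clip(
        np.sin(np.pi * (h - cfg.sunrise) / (cfg.sunset - cfg.sunrise)), 0.0, None
    ) * ((h >= cfg.sunrise) & (h < cfg.sunset))
    for year in range(cfg.n_years):
        rng = np.random.default_rng(streams[year])
        innov_sd = cfg.anomaly_sd * np.sqrt(max(1.0 - cfg.anomaly_ar1**2, 1e-12))
        anomaly = np.empty(cfg.season_days)
        anomaly[0] = rng.normal(0.0, cfg.anomaly_sd) if cfg.anomaly_sd else 0.0
        for i in range(1, cfg.season_days):
            anomaly[i] = cfg.anomaly_ar1 * anomaly[i - 1] + rng.normal(0.0, innov_sd)
        temp = (
            seasonal[:, None]
            + anomaly[:, None]
            + diurnal[None, :]
            + rng.normal(0.0, cfg.hourly_noise_sd, (cfg.season_days, 24))
        )
        rh = (
            cfg.rh_base
            - cfg.rh_diurnal_amplitude * np.cos(2 * np.pi * (h - 2.0) / 24.0)[None, :]
            - cfg.rh_coupling_slope * anomaly[:, None]
            + rng.normal(0.0, 2.0, (cfg.season_days, 24))
        )
        rh = np.clip(rh, 5.0, 100.0)
        cloud_factor = np.clip(1.0 + 0.10 * anomaly, 0.15, 1.3)
        rad = cfg.radiation_peak_wm2 * daylight[None, :] * cloud_factor[:, None]
        rad = np.clip(rad * (1.0 + rng.normal(0.0, 0.05, rad.shape)), 0.0, None)
        rad[:, daylight == 0.0] = 0.0
        start = pd.Timestamp(cfg.start_dates[year % len(cfg.start_dates)])
        index = pd.date_range(start, periods=cfg.season_days * 24, freq="1h")
        frame = pd.DataFrame(
            {
                "temperature": temp.ravel(),
                "relative_humidity": rh.ravel(),
                "global_radiation": rad.ravel(),
            },
            index=index,
        )
        out.append(HourlyWeatherSeries(f"synthetic_{2016 + year}", frame))
    return out


def glasshouse_series(
    season_days: int = 135,
    day_temp: float = 25.0,
    night_temp: float = 18.0,
    day_rh: float = 60.0,
    night_rh: float = 80.0,
    day_start: float = 7.0,
    day_end: float = 23.0,
    start_date: str = "2018-11-01",
) -> HourlyWeatherSeries:
    """Static glasshouse program (fixed day/night temperature and RH)."""
    h = np.arange(24.0)
    is_day = (h >= day_start) & (h < day_end)
    temp = np.tile(np.where(is_day, day_temp, night_temp), season_days)
    rh = np.tile(np.where(is_day, day_rh, night_rh), season_days)
    rad = np.tile(np.where(is_day, 125.0, 0.0), season_days)
    index = pd.date_range(pd.Timestamp(start_date), periods=season_days * 24, freq="1h")
    frame = pd.DataFrame(
        {"temperature": temp, "relative_humidity": rh, "global_radiation": rad},
        index=index,
    )
    return HourlyWeatherSeries("glasshouse", frame)


# -- phenotypes ----------------------------------------------------------------


def _default_env_params() -> dict:
    # Field-like seasons inflect late (~68 DAS); the static glasshouse and the
    # averaged chamber regime drive development ~30 and ~20 days earlier.
    return {
        "field_2016": (220.0, 68.0, 9.0),
        "field_2017": (205.0, 67.0, 9.5),
        "field_2018": (210.0, 69.0, 9.0),
        "field_2019": (195.0, 66.5, 9.5),
        "glasshouse": (265.0, 38.0, 7.0),
        "chamber_avg": (245.0, 48.0, 8.0),
        "chamber_sim": (225.0, 68.0, 9.0),
    }


@dataclass
class PhenoGenConfig:
    """Phenotype-series structure: 11 genotypes × 7 environments by default,
    sampled twice weekly (days ≡ 0 and 3 mod 7, Mondays and Thursdays)."""

    n_genotypes: int = 11
    env_params: dict = field(default_factory=_default_env_params)
    genotype_sd_asym: float = 18.0
    genotype_sd_xmid: float = 2.5
    residual_sd: float = 5.0  # cm at full height; shrinks early in the season
    arma_ar: tuple = (0.4, 0.2)
    arma_ma: tuple = (0.3, 0.1)
    first_day: int = 7
    last_day: int = 115
    n_replicates: int = 2
    plants_per_replicate: int = 3
    replicate_sd: float = 1.5
    row_sd: float = 1.0
    position_sd: float = 1.0


def logistic3(x, asym, xmid, scal):
    """Three-parameter logistic y(x) = Asym / (1 + exp((xmid − x)/scal))."""
    return asym / (1.0 + np.exp((xmid - np.asarray(x, float)) / scal))


def sampling_days(first_day: int, last_day: int) -> np.ndarray:
    """Twice-weekly measurement days (Mondays and Thursdays)."""
    d = np.arange(first_day, last_day + 1)
    return d[(d % 7 == 0) | (d % 7 == 3)]


def _arma_noise(rng, ar, ma, shape, target_sd, burnin=100):
    """Stationary ARMA noise with marginal sd ``target_sd`` (100-step burn-in)."""
    ar = np.asarray(ar, float)
    ma = np.asarray(ma, float)
    proc = ArmaProcess(np.r_[1, -ar], np.r_[1, ma])
    scale = target_sd / np.sqrt(proc.acovf(1)[0])
    n = shape[-1]
    e = rng.standard_normal(tuple(shape[:-1]) + (n + burnin,)) * scale
    x = lfilter(np.r_[1, ma], np.r_[1, -ar], e, axis=-1)
    return x[..., burnin:]


def generate_phenotypes(
    config: PhenoGenConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Long-format plant-height table plus the truth record used to build it."""
    cfg = config or PhenoGenConfig()
    s_effects, s_resid, s_design = np.random.SeedSequence(seed).spawn(3)
    rng_eff = np.random.default_rng(s_effects)
    rng_res = np.random.default_rng(s_resid)
    rng_des = np.random.default_rng(s_design)

    genotypes = [f"g{i + 1:02d}" for i in range(cfg.n_genotypes)]
    g_asym = rng_eff.normal(0.0, cfg.genotype_sd_asym, cfg.n_genotypes)
    g_xmid = rng_eff.normal(0.0, cfg.genotype_sd_xmid, cfg.n_genotypes)
    g_asym -= g_asym.mean()  # random effects centred, as in the fitted model
    g_xmid -= g_xmid.mean()

    days = sampling_days(cfg.first_day, cfg.last_day)
    rows = []
    for env, (asym_e, xmid_e, scal_e) in cfg.env_params.items():
        rep_eff = rng_des.normal(0.0, cfg.replicate_sd, cfg.n_replicates)
        for gi, geno in enumerate(genotypes):
            curve = logistic3(days, asym_e + g_asym[gi], xmid_e + g_xmid[gi], scal_e)
            frac = 0.2 + 0.8 * curve / (asym_e + g_asym[gi])
            for rep in range(cfg.n_replicates):
                row_eff = rng_des.normal(0.0, cfg.row_sd)
                for plant in range(cfg.plants_per_replicate):
                    pos_eff = rng_des.normal(0.0, cfg.position_sd)
                    noise = _arma_noise(
                        rng_res, cfg.arma_ar, cfg.arma_ma, (len(days),),
                        cfg.residual_sd,
                    )
                    y = np.clip(curve + rep_eff[rep] + row_eff + pos_eff
                                + noise * frac, 0.0, None)
                    rows.append(
                        pd.DataFrame(
                            {
                                "genotype": geno,
                                "environment": env,
                                "das": days,
                                "replicate": rep + 1,
                                "row": f"r{rep + 1}_{gi % 4}",
                                "column": f"c{gi // 4}",
                                "position": plant + 1,
                                "plant_height": y,
                            }
                        )
                    )
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "env_params": dict(cfg.env_params),
        "genotype_asym": dict(zip(genotypes, g_asym)),
        "genotype_xmid": dict(zip(genotypes, g_xmid)),
        "residual_sd": cfg.residual_sd,
    }
    return table, truth


# -- tasseling -----------------------------------------------------------------


@dataclass
class TasselGenConfig:
    env_median_das: dict = field(
        default_factory=lambda: {
            "field_2016": 76.0,
            "field_2017": 74.0,
            "field_2018": 77.0,
            "field_2019": 73.0,
            "glasshouse": 45.0,
            "chamber_avg": 55.0,
            "chamber_sim": 75.0,
        }
    )
    onset_scale: float = 3.0  # logistic scale of per-plant onset spread, days
    n_plants: int = 110
    first_day: int = 7
    last_day: int = 115


def generate_tassel(
    config: TasselGenConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Percent of plants with a tassel per environment × measurement day.

    Per-plant tassel onset is a logistic-quantile draw around the environment
    median; percentages are non-decreasing in time by construction.
    """
    cfg = config or TasselGenConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    days = sampling_days(cfg.first_day, cfg.last_day)
    rows = []
    for env, median in cfg.env_median_das.items():
        u = rng.uniform(1e-9, 1 - 1e-9, cfg.n_plants)
        onset = median + cfg.onset_scale * np.log(u / (1.0 - u))
        pct = [(onset <= d).mean() * 100.0 for d in days]
        rows.append(pd.DataFrame({"environment": env, "das": days, "percent": pct}))
    return pd.concat(rows, ignore_index=True)


# -- homogeneity trial -----------------------------------------------------------


@dataclass
class HomogeneityGenConfig:
    """Spatial-homogeneity trial: 2 genotypes in each of 55 containers (two
    sides per container), soil groups of 25 reused / 25 top-exchanged /
    5 fully renewed containers, preculture labels from the preceding run.

    Variance components are planted on the square-root trait scale (the scale
    on which the decomposition model is fit); the stored trait is the square.
    Defaults plant shares of 0.70 genotype, 0.05 row, 0.25 residual.
    """

    n_containers: int = 55
    n_rows: int = 5
    n_cols: int = 11
    plants_per_side: int = 3
    genotypes: tuple = ("PHT77", "N22")
    n_precultures: int = 11
    grand_mean_sqrt: float = 12.0
    # total planted variance 4 with shares 0.70 genotype, 0.05 row, 0.25 residual
    genotype_diff_sqrt: float = 2.0 * np.sqrt(2.8)  # fixed-effect variance Δ²/4
    preculture_sd: float = 0.0
    column_sd: float = 0.0
    row_effect_sd: float = np.sqrt(0.2)
    replicate_sd: float = 0.0
    soil_sd: float = 0.0
    residual_sd: float = 1.0
    das: int = 50


def generate_homogeneity_trial(
    config: HomogeneityGenConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    cfg = config or HomogeneityGenConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    containers = np.arange(cfg.n_containers)
    rows = containers // cfg.n_cols
    cols = containers % cfg.n_cols
    soil = np.array(["reused"] * 25 + ["top_exchanged"] * 25 + ["renewed"] * 5)[
        : cfg.n_containers
    ]
    soil = rng.permutation(soil)
    precult = rng.integers(0, cfg.n_precultures, cfg.n_containers)

    eff_row = rng.normal(0.0, cfg.row_effect_sd, cfg.n_rows)
    eff_col = rng.normal(0.0, cfg.column_sd, cfg.n_cols)
    eff_pre = rng.normal(0.0, cfg.preculture_sd, cfg.n_precultures)
    eff_soil = {s: rng.normal(0.0, cfg.soil_sd) for s in np.unique(soil)}
    eff_rep = rng.normal(0.0, cfg.replicate_sd, cfg.plants_per_side)
    half = cfg.genotype_diff_sqrt / 2.0
    eff_geno = {cfg.genotypes[0]: +half, cfg.genotypes[1]: -half}

    recs = []
    for c in containers:
        sides = list(cfg.genotypes)
        rng.shuffle(sides)
        for side, geno in enumerate(sides, start=1):
            for rep in range(cfg.plants_per_side):
                y_sqrt = (
                    cfg.grand_mean_sqrt
                    + eff_geno[geno]
                    + eff_row[rows[c]]
                    + eff_col[cols[c]]
                    + eff_pre[precult[c]]
                    + eff_soil[soil[c]]
                    + eff_rep[rep]
                    + rng.normal(0.0, cfg.residual_sd)
                )
                recs.append(
                    {
                        "container": int(c),
                        "row": int(rows[c]),
                        "column": int(cols[c]),
                        "soil": soil[c],
                        "preculture": f"p{precult[c]:02d}",
                        "side": side,
                        "replicate": rep + 1,
                        "genotype": geno,
                        "das": cfg.das,
                        "plant_height": max(y_sqrt, 0.0) ** 2,
                    }
                )
    return pd.DataFrame.from_records(recs)


# -- repeatability structure -----------------------------------------------------


@dataclass
class RepeatabilityGenConfig:
    """Multi-environment table with planted genotype repeatability.

    Effects are planted on the square-root trait scale; the default
    σ²_genotype = σ²_residual = 1 plants R_genotype = 0.5.
    """

    n_genotypes: int = 11
    n_experiments: int = 5
    n_times: int = 8
    n_replicates: int = 2
    grand_mean_sqrt: float = 10.0
    genotype_sd: float = 1.0
    genotype_experiment_sd: float = 0.4
    genotype_time_sd: float = 0.4
    experiment_effect_sd: float = 1.5
    time_slope: float = 0.3
    residual_sd: float = 1.0

    @property
    def true_repeatability(self) -> float:
        return self.genotype_sd**2 / (self.genotype_sd**2 + self.residual_sd**2)


def generate_repeatability_table(
    config: RepeatabilityGenConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    cfg = config or RepeatabilityGenConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genos = [f"g{i + 1:02d}" for i in range(cfg.n_genotypes)]
    exps = [f"e{j + 1}" for j in range(cfg.n_experiments)]
    g = rng.normal(0.0, cfg.genotype_sd, cfg.n_genotypes)
    e = rng.normal(0.0, cfg.experiment_effect_sd, cfg.n_experiments)
    ge = rng.normal(0.0, cfg.genotype_experiment_sd, (cfg.n_genotypes, cfg.n_experiments))
    gt = rng.normal(
        0.0, cfg.genotype_time_sd, (cfg.n_genotypes, cfg.n_experiments, cfg.n_times)
    )
    recs = []
    for gi, geno in enumerate(genos):
        for ei, exp in enumerate(exps):
            for t in range(cfg.n_times):
                mean = (
                    cfg.grand_mean_sqrt
                    + g[gi]
                    + e[ei]
                    + cfg.time_slope * t
                    + ge[gi, ei]
                    + gt[gi, ei, t]
                )
                for rep in range(cfg.n_replicates):
                    y_sqrt = mean + rng.normal(0.0, cfg.residual_sd)
                    recs.append(
                        {
                            "genotype": geno,
                            "experiment": exp,
                            "experiment_time": f"{exp}_t{t:02d}",
                            "replicate": rep + 1,
                            "plant_height": max(y_sqrt, 0.0) ** 2,
                        }
                    )
    return pd.DataFrame.from_records(recs)
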