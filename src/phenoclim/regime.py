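"""Compile field weather into controlled-environment climate programs.

Two compilation modes are provided, mirroring the two ways a chamber season can
be programmed from field records:

``averaged``
    Each experiment week is built from the hour-wise *median* weekday profiles
    across several template years.  Among the seven median days, the one with
    the lowest daylight-mean temperature becomes the *cloudy* model day, the
    highest the *sunny* one, and the hour-wise mean over all seven the
    *normal* day.  Every week runs the same fixed sequence of
    3 normal / 2 sunny / 2 cloudy days.

``single_season``
    Each week is built from one template year only.  The normal day is the
    hour-wise mean of the week's seven real days; the sunny and cloudy model
    days are the individual real days with the highest and lowest
    daylight-mean temperature.  Each real day is classified
    sunny/cloudy/normal against the weekly daylight mean ± a band, and the
    emitted sequence preserves the week's day-type frequencies with same-type
    days placed consecutively (weather fronts persist for more than a day).

Humidity, light, wind and day-length schedules are programmed, not measured:
relative humidity ramps from 90 % at night to a 40 % (normal/sunny) or 50 %
(cloudy) plateau held for the central 5 h of the photoperiod; light follows a
per-day-type base intensity with a sinusoidal "cloud cover" window; wind
oscillates in fixed bands with the direction switched every 2 h; sunrise and
sunset move ±10 min per week with a reversal in midsummer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .weather import HourlyWeatherSeries, day_matrix

DAY_TYPES = ("normal", "sunny", "cloudy")

#: Fixed weekly sequence for averaged mode, Monday-first
#: (normal: Friday, Tuesday, Wednesday; cloudy: Sunday, Thursday;
#: sunny: Saturday, Monday).
DEFAULT_AVERAGED_PATTERN = (
    "sunny",  # Monday
    "normal",  # Tuesday
    "normal",  # Wednesday
    "cloudy",  # Thursday
    "normal",  # Friday
    "sunny",  # Saturday
    "cloudy",  # Sunday
)


class RegimeConfigError(ValueError):
    pass


class RegimeCompilationError(RuntimeError):
    pass


@dataclass
class RegimeConfig:
    """Tunable parameters of the chamber program.

    Times are fractional clock hours.  Defaults follow the facility program:
    90 % RH at night dropping to 40 % (50 % on cloudy days) over a central 5 h
    plateau; base light intensities 940/961/319 µmol m⁻² s⁻¹ with 5/2/8 h of
    sinusoidal cloud cover for normal/sunny/cloudy days; wind 10–20 % at
    night, 30–50 % ramps morning/afternoon, constant 50 % midday, direction
    switched every 2 h; day length changing by ±10 min per week with a
    midsummer reversal; temperature setpoints clamped to 0–47.5 °C.
    """

    base_sunrise: float = 6.0
    base_sunset: float = 20.0
    day_length_step_min: float = 10.0
    reversal_week: int = 7  # ~June 21 for a season starting May 2

    night_rh: float = 90.0
    midday_rh_normal_sunny: float = 40.0
    midday_rh_cloudy: float = 50.0
    central_plateau_hours: float = 5.0

    light_intensity: dict = field(
        default_factory=lambda: {"normal": 940.0, "sunny": 961.0, "cloudy": 319.0}
    )
    cloud_hours: dict = field(
        default_factory=lambda: {"normal": 5.0, "sunny": 2.0, "cloudy": 8.0}
    )
    cloud_depth_fraction: float = 1.0 / 3.0  # sinusoid dips to this × base
    cloud_sine_period_hours: float = 2.0

    wind_night_band: tuple = (10.0, 20.0)
    wind_ramp_band: tuple = (30.0, 50.0)
    wind_midday: float = 50.0
    wind_direction_switch_hours: int = 2

    clamp_bounds: tuple = (0.0, 47.5)
    averaged_pattern: tuple = DEFAULT_AVERAGED_PATTERN
    single_season_band: float = 1.0  # °C around weekly daylight mean
    start_timestamp: str = "2000-05-02T00:00:00"


@dataclass
class DayProfile:
    day_type: str
    temperature_profile: np.ndarray  # 24 hourly °C values
    source: str = "averaged"

    def __post_init__(self) -> None:
        self.temperature_profile = np.asarray(self.temperature_profile, float)
        if self.temperature_profile.shape != (24,):
            raise RegimeConfigError("a day profile needs exactly 24 hourly values")
        if not np.all(np.isfinite(self.temperature_profile)):
            raise RegimeConfigError("day profile contains non-finite values")


@dataclass
class WeekRegime:
    week_index: int
    day_sequence: tuple  # 7 labels
    day_programs: dict  # day_type -> DayProfile
    sunrise: float
    sunset: float

    def __post_init__(self) -> None:
        if len(self.day_sequence) != 7:
            raise RegimeConfigError("a week needs exactly 7 day labels")
        for label in self.day_sequence:
            if label not in self.day_programs:
                raise RegimeConfigError(f"no program for day type {label!r}")

    def day_type_counts(self) -> dict:
        return {t: self.day_sequence.count(t) for t in DAY_TYPES}


@dataclass
class SeasonRegime:
    mode: str  # averaged | single_season
    weeks: list  # ordered WeekRegime
    config: RegimeConfig
    clamp_events: int = 0
    notes: list = field(default_factory=list)

    def n_days(self) -> int:
        return 7 * len(self.weeks)


# -- daylight statistics ------------------------------------------------------


def daylight_mean(profile: np.ndarray, sunrise: float, sunset: float) -> float:
    """Mean temperature over daylight hours (sunrise ≤ h < sunset)."""
    hours = np.arange(24)
    mask = (hours >= sunrise) & (hours < sunset)
    return float(np.asarray(profile, float)[mask].mean())


# -- model-day construction ---------------------------------------------------


def median_weekday_profiles(
    years: list[HourlyWeatherSeries], calendar_week: int
) -> list[DayProfile]:
    """Hour-wise median profile per weekday slot across template years.

    For week *w*, weekday slot *d* collects day 7w+d of every year and takes
    the per-hour median over the years.
    """
    if len(years) < 2:
        raise RegimeConfigError("median weekday profiles need at least 2 years")
    mats = [day_matrix(y) for y in years]
    first, last = 7 * calendar_week, 7 * calendar_week + 6
    for y, m in zip(years, mats):
        if m.shape[0] <= last:
            raise RegimeConfigError(
                f"{y.environment_id}: does not contain calendar week {calendar_week}"
            )
    out = []
    for d in range(7):
        stack = np.stack([m[first + d] for m in mats])
        if np.isnan(stack).any():
            raise RegimeConfigError(
                f"week {calendar_week} day {d}: gaps present; impute before compiling"
            )
        out.append(
            DayProfile("normal", np.median(stack, axis=0), source="median-of-years")
        )
    return out


def select_model_days(
    median_days: list[DayProfile], sunrise: float, sunset: float
) -> dict:
    """Pick the cloudy / sunny / normal model days from 7 median days.

    Cloudy = lowest daylight-mean temperature, sunny = highest, normal =
    hour-wise mean over all seven.  Ties break toward the earlier weekday.
    """
    if len(median_days) != 7:
        raise RegimeConfigError("expected 7 median days")
    means = np.array(
        [daylight_mean(d.temperature_profile, sunrise, sunset) for d in median_days]
    )
    lo = int(np.argmin(means))  # argmin/argmax take the first (earliest) on ties
    hi = int(np.argmax(means))
    if (means == means[lo]).sum() > 1 or (means == means[hi]).sum() > 1:
        warnings.warn(
            "tie in daylight-mean ranking; earliest weekday wins", stacklevel=2
        )
    normal = np.mean([d.temperature_profile for d in median_days], axis=0)
    return {
        "cloudy": DayProfile(
            "cloudy", median_days[lo].temperature_profile, median_days[lo].source
        ),
        "sunny": DayProfile(
            "sunny", median_days[hi].temperature_profile, median_days[hi].source
        ),
        "normal": DayProfile("normal", normal, source="averaged"),
    }


def build_averaged_week(
    model_days: dict,
    week_index: int,
    sunrise: float,
    sunset: float,
    pattern: tuple = DEFAULT_AVERAGED_PATTERN,
) -> WeekRegime:
    """Week with the fixed 3 normal / 2 sunny / 2 cloudy sequence."""
    counts = {t: pattern.count(t) for t in DAY_TYPES}
    if len(pattern) != 7 or counts != {"normal": 3, "sunny": 2, "cloudy": 2}:
        raise RegimeConfigError(
            f"pattern multiset must be 3 normal / 2 sunny / 2 cloudy, got {counts}"
        )
    return WeekRegime(week_index, tuple(pattern), dict(model_days), sunrise, sunset)


def classify_week_days(
    template_week: np.ndarray, sunrise: float, sunset: float, band: float
) -> list[str]:
    """Classify each of 7 real days as sunny / cloudy / normal.

    A day is sunny if its daylight-mean temperature exceeds the weekly mean of
    the daylight means by more than ``band`` °C, cloudy if it falls short by
    more than ``band``, and normal otherwise.
    """
    means = np.array([daylight_mean(day, sunrise, sunset) for day in template_week])
    center = means.mean()
    labels = []
    for m in means:
        if m > center + band:
            labels.append("sunny")
        elif m < center - band:
            labels.append("cloudy")
        else:
            labels.append("normal")
    return labels


def build_single_season_week(
    template_year: HourlyWeatherSeries,
    calendar_week: int,
    sunrise: float,
    sunset: float,
    band: float = 1.0,
) -> WeekRegime:
    """Week mirroring one template year's day-type frequencies and run order.

    Normal = hour-wise mean over the week's 7 real days; sunny/cloudy = the
    individual real days with highest/lowest daylight-mean temperature.  The
    emitted sequence keeps each day type's classification count, with
    same-type days placed consecutively in order of first occurrence.
    """
    mat = day_matrix(template_year)
    first, last = 7 * calendar_week, 7 * calendar_week + 6
    if mat.shape[0] <= last:
        raise RegimeConfigError(
            f"{template_year.environment_id}: no calendar week {calendar_week}"
        )
    week = mat[first : last + 1]
    if np.isnan(week).any():
        raise RegimeConfigError(
            f"week {calendar_week}: template week has gaps; impute first"
        )
    means = np.array([daylight_mean(day, sunrise, sunset) for day in week])
    labels = classify_week_days(week, sunrise, sunset, band)
    programs = {
        "normal": DayProfile("normal", week.mean(axis=0), source="averaged"),
        "sunny": DayProfile(
            "sunny", week[int(np.argmax(means))], source="single template date"
        ),
        "cloudy": DayProfile(
            "cloudy", week[int(np.argmin(means))], source="single template date"
        ),
    }
    # group same-type days into maximal runs, ordered by first occurrence
    order = []
    for label in labels:
        if label not in order:
            order.append(label)
    sequence = tuple(t for t in order for _ in range(labels.count(t)))
    return WeekRegime(calendar_week, sequence, programs, sunrise, sunset)


# -- daily schedules ----------------------------------------------------------


def day_length_for_week(
    week_index: int,
    base_sunrise: float,
    base_sunset: float,
    reversal_week: int,
    step_min: float = 10.0,
) -> tuple[float, float]:
    """Weekly photoperiod rule: sunrise −10 min and sunset +10 min per week up
    to the reversal week, mirrored afterwards."""
    shift_weeks = week_index if week_index <= reversal_week else 2 * reversal_week - week_index
    shift = step_min / 60.0 * shift_weeks
    return base_sunrise - shift, base_sunset + shift


def humidity_day(
    day_type: str,
    sunrise: float,
    sunset: float,
    config: RegimeConfig | None = None,
) -> np.ndarray:
    """24 hourly RH setpoints for one day.

    90 % at night; linear ramp from sunrise down to the plateau value (40 %
    normal/sunny, 50 % cloudy) held for the central plateau hours of the
    photoperiod; linear ramp back to 90 % at sunset.
    """
    cfg = config or RegimeConfig()
    if day_type not in DAY_TYPES:
        raise RegimeConfigError(f"unknown day type {day_type!r}")
    if not sunrise < sunset:
        raise RegimeConfigError("sunrise must precede sunset")
    if sunset - sunrise <= cfg.central_plateau_hours:
        raise RegimeConfigError("photoperiod shorter than the humidity plateau")
    plateau = (
        cfg.midday_rh_cloudy if day_type == "cloudy" else cfg.midday_rh_normal_sunny
    )
    mid = 0.5 * (sunrise + sunset)
    ps = mid - cfg.central_plateau_hours / 2.0
    pe = mid + cfg.central_plateau_hours / 2.0
    hours = np.arange(24, dtype=float)
    rh = np.full(24, cfg.night_rh)
    ramp_dn = (hours > sunrise) & (hours < ps)
    rh[ramp_dn] = cfg.night_rh + (plateau - cfg.night_rh) * (
        (hours[ramp_dn] - sunrise) / (ps - sunrise)
    )
    rh[(hours >= ps) & (hours <= pe)] = plateau
    ramp_up = (hours > pe) & (hours < sunset)
    rh[ramp_up] = plateau + (cfg.night_rh - plateau) * (
        (hours[ramp_up] - pe) / (sunset - pe)
    )
    return rh


def light_day(
    day_type: str,
    sunrise: float,
    sunset: float,
    config: RegimeConfig | None = None,
) -> np.ndarray:
    """24 hourly light-intensity setpoints (µmol m⁻² s⁻¹) for one day.

    Base intensity per day type within the photoperiod, zero outside; inside a
    centrally placed cloud-cover window the intensity is modulated by a
    sinusoid dipping from the base down to ``cloud_depth_fraction`` × base.
    """
    cfg = config or RegimeConfig()
    if day_type not in cfg.light_intensity:
        raise RegimeConfigError(f"unknown day type {day_type!r}")
    base = cfg.light_intensity[day_type]
    window = cfg.cloud_hours[day_type]
    if sunset - sunrise < window:
        raise RegimeConfigError("photoperiod shorter than the cloud-cover window")
    mid = 0.5 * (sunrise + sunset)
    w0, w1 = mid - window / 2.0, mid + window / 2.0
    hours = np.arange(24, dtype=float)
    out = np.where((hours >= sunrise) & (hours < sunset), base, 0.0)
    in_window = (hours >= w0) & (hours < w1)
    depth = base * (1.0 - cfg.cloud_depth_fraction)
    phase = 2.0 * np.pi * (hours - w0) / cfg.cloud_sine_period_hours
    out[in_window] -= depth * 0.5 * (1.0 - np.cos(phase[in_window]))
    return out


def wind_day(
    sunrise: float, sunset: float, config: RegimeConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """24 hourly wind setpoints (% of maximal rotation) and direction flags.

    Night hours oscillate between 10 and 20 %; the morning ramps from 30 to
    50 % (sunrise → midday plateau), midday is a constant 50 %, the afternoon
    ramps back from 50 to 30 %; the direction flag alternates every 2 h.
    """
    cfg = config or RegimeConfig()
    lo_n, hi_n = cfg.wind_night_band
    lo_r, hi_r = cfg.wind_ramp_band
    mid = 0.5 * (sunrise + sunset)
    ps = mid - cfg.central_plateau_hours / 2.0
    pe = mid + cfg.central_plateau_hours / 2.0
    hours = np.arange(24, dtype=float)
    blocks = (hours // cfg.wind_direction_switch_hours).astype(int)
    wind = np.where(blocks % 2 == 0, lo_n, hi_n)  # night oscillation
    morning = (hours >= sunrise) & (hours < ps)
    wind = wind.astype(float)
    wind[morning] = lo_r + (hi_r - lo_r) * (hours[morning] - sunrise) / (ps - sunrise)
    wind[(hours >= ps) & (hours <= pe)] = cfg.wind_midday
    afternoon = (hours > pe) & (hours < sunset)
    wind[afternoon] = hi_r - (hi_r - lo_r) * (hours[afternoon] - pe) / (sunset - pe)
    direction = np.where(blocks % 2 == 0, 1, -1)
    return wind, direction


# -- season compilation -------------------------------------------------------


def compile_season_regime(
    mode: str,
    years: list[HourlyWeatherSeries] | None = None,
    template_year: HourlyWeatherSeries | None = None,
    n_weeks: int | None = None,
    config: RegimeConfig | None = None,
) -> SeasonRegime:
    """Compile a full-season chamber program.

    ``averaged`` needs ≥2 template years, ``single_season`` one template year.
    ``n_weeks`` defaults to the number of complete weeks available.
    """
    cfg = config or RegimeConfig()
    weeks: list[WeekRegime] = []
    notes: list[str] = []
    if mode == "averaged":
        if not years or len(years) < 2:
            raise RegimeConfigError("averaged mode needs at least 2 template years")
        avail = min(day_matrix(y).shape[0] for y in years) // 7
    elif mode == "single_season":
        if template_year is None:
            raise RegimeConfigError("single_season mode needs a template year")
        avail = day_matrix(template_year).shape[0] // 7
    else:
        raise RegimeConfigError(f"unknown mode {mode!r}")
    n_weeks = avail if n_weeks is None else min(n_weeks, avail)
    if n_weeks < 1:
        raise RegimeCompilationError("no complete week available to compile")
    for w in range(n_weeks):
        sunrise, sunset = day_length_for_week(
            w, cfg.base_sunrise, cfg.base_sunset, cfg.reversal_week,
            cfg.day_length_step_min,
        )
        try:
            if mode == "averaged":
                med = median_weekday_profiles(years, w)
                model = select_model_days(med, sunrise, sunset)
                week = build_averaged_week(
                    model, w, sunrise, sunset, cfg.averaged_pattern
                )
            else:
                week = build_single_season_week(
                    template_year, w, sunrise, sunset, cfg.single_season_band
                )
                if len(set(week.day_sequence)) == 1:
                    notes.append(
                        f"week {w}: single-type week ({week.day_sequence[0]})"
                    )
        except Exception as exc:  # name the failing week
            raise RegimeCompilationError(f"week {w}: {exc}") from exc
        weeks.append(week)
    regime = SeasonRegime(mode=mode, weeks=weeks, config=cfg, notes=notes)
    regime.clamp_events = int(
        np.sum(
            [
                (p.temperature_profile < cfg.clamp_bounds[0]).sum()
                + (p.temperature_profile > cfg.clamp_bounds[1]).sum()
                for wk in weeks
                for p in wk.day_programs.values()
            ]
        )
    )
    return regime


def regime_setpoints(regime: SeasonRegime) -> pd.DataFrame:
    """Hourly setpoint table for the whole season.

    Columns: set_temperature (clamped to facility bounds), set_rh,
    set_light_umol, set_wind_pct, wind_direction, day_type; one row per hour,
    indexed by timestamp.
    """
    cfg = regime.config
    rows_t, rows_rh, rows_li, rows_w, rows_dir, rows_ty = [], [], [], [], [], []
    for wk in regime.weeks:
        wind, direction = wind_day(wk.sunrise, wk.sunset, cfg)
        for label in wk.day_sequence:
            prof = np.clip(
                wk.day_programs[label].temperature_profile,
                cfg.clamp_bounds[0],
                cfg.clamp_bounds[1],
            )
            rows_t.append(prof)
            rows_rh.append(humidity_day(label, wk.sunrise, wk.sunset, cfg))
            rows_li.append(light_day(label, wk.sunrise, wk.sunset, cfg))
            rows_w.append(wind)
            rows_dir.append(direction)
            rows_ty.extend([label] * 24)
    start = pd.Timestamp(cfg.start_timestamp)
    n = 24 * 7 * len(regime.weeks)
    index = pd.date_range(start, periods=n, freq="1h")
    return pd.DataFrame(
        {
            "set_temperature": np.concatenate(rows_t),
            "set_rh": np.concatenate(rows_rh),
            "set_light_umol": np.concatenate(rows_li),
            "set_wind_pct": np.concatenate(rows_w),
            "wind_direction": np.concatenate(rows_dir),
            "day_type": rows_ty,
        },
        index=index,
    )


def regime_to_series(regime: SeasonRegime, environment_id: str) -> HourlyWeatherSeries:
    """View the compiled program as an hourly weather series (for comparisons)."""
    table = regime_setpoints(regime)
    frame = pd.DataFrame(
        {
            "temperature": table["set_temperature"].to_numpy(),
            "relative_humidity": table["set_rh"].to_numpy(),
            "global_radiation": table["set_light_umol"].to_numpy() * 0.5,
        },
        index=table.index,
    )
    return HourlyWeatherSeries(environment_id, frame)


def export_regime(regime: SeasonRegime, path) -> None:
    """Write the setpoint CSV plus a JSON metadata sidecar (<path>.meta.json)."""
    table = regime_setpoints(regime)
    out = table.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)
    meta = {
        "mode": regime.mode,
        "n_weeks": len(regime.weeks),
        "clamp_events": regime.clamp_events,
        "notes": regime.notes,
        "day_sequences": [list(w.day_sequence) for w in regime.weeks],
        "config": {
            k: v
            for k, v in asdict(regime.config).items()
            if not isinstance(v, np.ndarray)
        },
    }
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=list)
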