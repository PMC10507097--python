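"""Derived environmental variables and environment-similarity metrics.

Covers three quantities used to compare a chamber regime with the field season
it emulates:

* saturation vapor pressure (Arden Buck formula) and vapor pressure deficit,
* cumulative thermal time — developmental time scaled by a maize-specific
  Arrhenius-type temperature response normalised to a constant 20 °C reference
  (one thermal-time day = one calendar day at 20 °C),
* pairwise channel similarity (Pearson r, R², two-sided p, RMSE) between two
  environments aligned by experiment-relative hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weather import HourlyWeatherSeries


@dataclass(frozen=True)
class VPDParams:
    """Arden Buck saturation-vapor-pressure constants (over water)."""

    aw: float = 6.1121  # hPa
    bw: float = 18.678
    cw: float = 257.14  # °C
    dw: float = 234.5  # °C


@dataclass(frozen=True)
class ThermalTimeParams:
    """Maize temperature-response constants for thermal-time scaling.

    ``minus_dHA`` is the (negative) enthalpy of activation −ΔH_A in J mol⁻¹;
    ``T20`` the 20 °C reference in K; ``To`` the maize-specific maximum
    temperature in K; ``alpha`` a unitless shape parameter.
    """

    minus_dHA: float = -73_900.0
    T20: float = 293.0
    To: float = 306.4
    R_gas: float = 8.314
    alpha: float = 3.5


DEFAULT_VPD = VPDParams()
DEFAULT_TT = ThermalTimeParams()

CELSIUS_TO_KELVIN = 273.15


def saturation_vapor_pressure(temperature_c, params: VPDParams = DEFAULT_VPD):
    """Saturation vapor pressure over water in hPa (Buck formula).

    es(T) = aw · exp((bw − T/dw) · T / (cw + T)), T in °C.  At 0 °C the
    exponent vanishes and es equals aw exactly.
    """
    t = np.asarray(temperature_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    if np.any(t < -40.0) or np.any(t > 60.0):
        raise ValueError("temperature outside physical range (-40..60 °C)")
    es = params.aw * np.exp((params.bw - t / params.dw) * t / (params.cw + t))
    return es if es.ndim else float(es)


def vpd(temperature_c, relative_humidity, params: VPDParams = DEFAULT_VPD):
    """Vapor pressure deficit in kPa from air temperature (°C) and RH (%)."""
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("relative humidity must be within [0, 100] %")
    es_hpa = saturation_vapor_pressure(temperature_c, params)
    out = np.asarray(es_hpa) * (1.0 - rh / 100.0) / 10.0
    return out if out.ndim else float(out)


def _response(t_kelvin, p: ThermalTimeParams):
    """Unnormalised temperature response f(T) of the thermal-time model."""
    t = np.asarray(t_kelvin, dtype=float)
    k20 = np.exp(p.minus_dHA / (p.R_gas * p.T20))
    num = t * np.exp(p.minus_dHA / (p.R_gas * t))
    den = 1.0 + k20 ** (p.alpha * (1.0 - t / p.To))
    return num / den


def thermal_time_increment(t_kelvin, params: ThermalTimeParams = DEFAULT_TT):
    """Thermal-time accrued in one hour at temperature T (K).

    (1/24) · f(T)/f(T20); exactly 1/24 at T = T20 = 293 K, so a day at a
    constant 20 °C accumulates one thermal-time day.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("temperature must be finite and positive (Kelvin)")
    out = _response(t, params) / _response(params.T20, params) / 24.0
    return out if out.ndim else float(out)


def cumulative_thermal_time(
    series: HourlyWeatherSeries, params: ThermalTimeParams = DEFAULT_TT
) -> pd.DataFrame:
    """Running thermal time over a gap-filled season.

    Returns a DataFrame indexed like the series with columns ``increment``,
    ``cumulative`` (per hour) and ``experiment_day``; the per-day totals
    (thermal-time day profiles) are obtainable with :func:`daily_thermal_time`.
    """
    if series.has_gaps:
        raise ValueError(
            f"{series.environment_id}: series has gaps; run impute_gaps first"
        )
    inc = thermal_time_increment(series.temperature + CELSIUS_TO_KELVIN, params)
    return pd.DataFrame(
        {
            "increment": inc,
            "cumulative": np.cumsum(inc),
            "experiment_day": series.experiment_day,
        },
        index=series.timestamps,
    )


def daily_thermal_time(tt: pd.DataFrame) -> pd.Series:
    """Per-day thermal-time totals from :func:`cumulative_thermal_time` output."""
    return tt.groupby("experiment_day")["increment"].sum()


# -- environment similarity --------------------------------------------------


@dataclass(frozen=True)
class EnvironmentComparison:
    environment_a: str
    environment_b: str
    channel: str
    pearson_r: float
    r_squared: float
    p_value: float
    rmse: float
    n: int
    alignment: str = "experiment-relative hour, truncated to shorter"

    def to_dict(self) -> dict:
        return {
            "a": self.environment_a,
            "b": self.environment_b,
            "channel": self.channel,
            "r": self.pearson_r,
            "r2": self.r_squared,
            "p": self.p_value,
            "rmse": self.rmse,
            "n": self.n,
        }


def _channel_values(series: HourlyWeatherSeries, channel: str) -> np.ndarray:
    if channel == "temperature":
        return series.temperature
    if channel == "vpd":
        return np.asarray(vpd(series.temperature, series.relative_humidity))
    if channel == "tt_day":
        tt = cumulative_thermal_time(series)
        return daily_thermal_time(tt).to_numpy()
    raise ValueError(f"unknown channel {channel!r}")


def compare_environments(
    a: HourlyWeatherSeries,
    b: HourlyWeatherSeries,
    channel: str = "temperature",
    include_imputed: bool = False,
    min_overlap: int = 48,
) -> EnvironmentComparison:
    """Similarity of two environments on one channel.

    Hour k (or day k for ``tt_day``) of environment A is paired with hour k of
    environment B, counted from each experiment's season start; unequal lengths
    are truncated to the shorter.  By default, hours whose value in either
    environment was imputed are excluded.
    """
    xa = _channel_values(a, channel)
    xb = _channel_values(b, channel)
    n = min(len(xa), len(xb))
    xa, xb = xa[:n], xb[:n]
    keep = np.isfinite(xa) & np.isfinite(xb)
    if not include_imputed and channel != "tt_day":
        keep &= ~a.imputed_mask()[:n]
        keep &= ~b.imputed_mask()[:n]
    xa, xb = xa[keep], xb[keep]
    threshold = min_overlap if channel != "tt_day" else max(min_overlap // 24, 2)
    if len(xa) < threshold:
        raise ValueError(
            f"overlap of {len(xa)} below the minimum of {threshold} for {channel}"
        )
    if np.std(xa) == 0 or np.std(xb) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(xa, xb)
    rmse = float(np.sqrt(np.mean((xa - xb) ** 2)))
    return EnvironmentComparison(
        environment_a=a.environment_id,
        environment_b=b.environment_id,
        channel=channel,
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        p_value=float(p),
        rmse=rmse,
        n=int(len(xa)),
    )
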