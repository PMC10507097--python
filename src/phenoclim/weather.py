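"""Hourly environmental sensor records: reading, validation, gap filling, slicing.

The central container is :class:`HourlyWeatherSeries`, a thin wrapper around a
pandas DataFrame indexed by hourly local-time timestamps with the channels
``temperature`` (°C), ``relative_humidity`` (%) and, optionally,
``global_radiation`` (W m⁻²).  Timestamps are local civil clock time; chamber
programs are defined on clock hours, so no daylight-saving arithmetic is done.

Hours missing from the raw record are *flagged* at read time (kept in
``series.gaps``) and only filled by an explicit :func:`impute_gaps` call, so
downstream comparisons can exclude imputed hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CHANNELS = ("temperature", "relative_humidity", "global_radiation")
MANDATORY = ("temperature", "relative_humidity")

CSV_COLUMNS = ["timestamp", "temperature", "relative_humidity", "global_radiation"]


class WeatherFormatError(ValueError):
    """Malformed input file (missing column, unparsable timestamp)."""


class WeatherDataError(ValueError):
    """Structurally valid file with invalid content (non-monotone time, bad RH)."""


class ImputationError(ValueError):
    """Gap that cannot be (or should not be) linearly filled."""


@dataclass
class HourlyWeatherSeries:
    """One environment's hourly weather record over a season.

    Attributes
    ----------
    environment_id
        Label of the environment (e.g. a field season or a chamber run).
    frame
        DataFrame indexed by an hourly DatetimeIndex with columns
        ``temperature``, ``relative_humidity`` and optionally
        ``global_radiation``.  Flagged-but-unfilled gaps appear as NaN rows.
    gaps
        Timestamps that were absent (or empty) in the raw record.
    """

    environment_id: str
    frame: pd.DataFrame
    gaps: pd.DatetimeIndex = field(
        default_factory=lambda: pd.DatetimeIndex([], dtype="datetime64[ns]")
    )

    def __post_init__(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise WeatherDataError("frame must be indexed by timestamps")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if np.any(deltas <= 0):
                raise WeatherDataError(
                    f"{self.environment_id}: timestamps not strictly increasing"
                )
            if np.any(deltas % (3600 * 10**9) != 0):
                raise WeatherDataError(
                    f"{self.environment_id}: timestamps not on an hourly lattice"
                )
        rh = self.frame["relative_humidity"].to_numpy(float)
        ok = np.isnan(rh) | ((rh >= 0.0) & (rh <= 100.0))
        if not ok.all():
            raise WeatherDataError(
                f"{self.environment_id}: relative humidity outside [0, 100]"
            )

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def temperature(self) -> np.ndarray:
        return self.frame["temperature"].to_numpy(float)

    @property
    def relative_humidity(self) -> np.ndarray:
        return self.frame["relative_humidity"].to_numpy(float)

    @property
    def global_radiation(self) -> np.ndarray | None:
        if "global_radiation" not in self.frame.columns:
            return None
        return self.frame["global_radiation"].to_numpy(float)

    @property
    def experiment_day(self) -> np.ndarray:
        """Integer day index relative to the season start (day 0 = first day).

        Day boundaries are midnight local time.
        """
        idx = self.frame.index
        day0 = idx[0].normalize()
        return ((idx.normalize() - day0) / pd.Timedelta(days=1)).astype(int).to_numpy()

    @property
    def has_gaps(self) -> bool:
        return bool(self.frame[list(MANDATORY)].isna().any().any())

    def imputed_mask(self) -> np.ndarray:
        """Boolean mask (per hour) of values that came from imputation."""
        return self.frame.index.isin(self.gaps)


# -- I/O -------------------------------------------------------------------


def read_hourly_weather(path, environment_id: str) -> HourlyWeatherSeries:
    """Read a CSV of hourly sensor records.

    Expected header: ``timestamp,temperature,relative_humidity,global_radiation``
    (radiation optional).  Missing hours and empty fields are flagged as gaps —
    the returned series still contains NaN there; call :func:`impute_gaps` to
    fill them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "timestamp" not in df.columns:
        raise WeatherFormatError(f"{path}: missing 'timestamp' column")
    for col in MANDATORY:
        if col not in df.columns:
            raise WeatherFormatError(f"{path}: missing mandatory column '{col}'")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"{path}: unparsable timestamps: {exc}") from None
    if ts.isna().any():
        raise WeatherFormatError(f"{path}: unparsable timestamps")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise WeatherDataError(f"{path}: timestamps not strictly increasing")

    cols = [c for c in CHANNELS if c in df.columns]
    data = df[cols].copy()
    data.index = pd.DatetimeIndex(ts)
    # Re-index onto the full hourly lattice; absent rows become NaN gaps.
    full = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="1h")
    data = data.reindex(full)
    gap_mask = data[list(MANDATORY)].isna().any(axis=1)
    gaps = data.index[gap_mask]
    return HourlyWeatherSeries(environment_id=environment_id, frame=data, gaps=gaps)


def write_hourly_weather(series: HourlyWeatherSeries, path) -> None:
    """Write the CSV dialect that :func:`read_hourly_weather` consumes.

    Floats are written with shortest round-trip repr, so write→read is
    bit-identical on every channel.
    """
    out = series.frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)


# -- gap filling -----------------------------------------------------------


def impute_gaps(
    series: HourlyWeatherSeries, max_gap_hours: int = 24
) -> HourlyWeatherSeries:
    """Linearly interpolate every channel across each flagged gap.

    Endpoints (observed hours) are left unchanged.  A gap at either series
    boundary has no bracketing observation and raises; a gap longer than
    ``max_gap_hours`` raises after emitting a warning.
    """
    frame = series.frame
    obs = ~frame[list(MANDATORY)].isna().any(axis=1).to_numpy()
    if obs.all():
        return series
    if not obs[0] or not obs[-1]:
        raise ImputationError(
            f"{series.environment_id}: gap at series boundary cannot be interpolated"
        )
    # longest run of consecutive missing hours
    missing_runs = np.flatnonzero(np.diff(np.r_[False, ~obs, False]))
    lengths = missing_runs[1::2] - missing_runs[0::2]
    if lengths.size and lengths.max() > max_gap_hours:
        warnings.warn(
            f"{series.environment_id}: gap of {lengths.max()} h exceeds the "
            f"{max_gap_hours} h imputation cap",
            stacklevel=2,
        )
        raise ImputationError(
            f"{series.environment_id}: gap exceeds {max_gap_hours} h cap"
        )
    filled = frame.interpolate(method="time", limit_area="inside")
    return replace(series, frame=filled)


def slice_season(
    series: HourlyWeatherSeries, start_day: int, end_day: int
) -> HourlyWeatherSeries:
    """Contiguous hourly sub-series covering experiment days start..end inclusive.

    The result's experiment_day is re-based to 0.
    """
    days = series.experiment_day
    mask = (days >= start_day) & (days <= end_day)
    if not mask.any():
        raise WeatherDataError(
            f"{series.environment_id}: empty slice [{start_day}, {end_day}]"
        )
    frame = series.frame.loc[mask]
    gaps = series.gaps[series.gaps.isin(frame.index)]
    return HourlyWeatherSeries(series.environment_id, frame.copy(), gaps)


def day_matrix(series: HourlyWeatherSeries, channel: str = "temperature") -> np.ndarray:
    """Reshape a complete season into an (n_days, 24) array for one channel.

    Requires whole days (season starting at 00:00 with 24 h per day).
    """
    vals = series.frame[channel].to_numpy(float)
    if len(vals) % 24 != 0 or series.timestamps[0].hour != 0:
        raise WeatherDataError(
            f"{series.environment_id}: series is not whole midnight-aligned days"
        )
    return vals.reshape(-1, 24)
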