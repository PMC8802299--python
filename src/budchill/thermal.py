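"""Hourly thermal-time models for bud dormancy.

Three accumulation models operate on a contiguous hourly air-temperature
series:

* **Chill hours (CH)** — Weinberger-style counting: each hour whose
  temperature lies in an effective chilling band (default 0 < T <= 7.2 degC)
  contributes one unit.
* **Chill portions (CP)** — the two-step dynamic model: a thermally labile
  intermediate relaxes toward a temperature-dependent equilibrium at a
  temperature-dependent rate; whenever the intermediate completes (reaches 1),
  a temperature-dependent fraction is banked irreversibly as a chill portion
  and the remainder carries over.  Chilling is therefore partially reversible
  by warm spells, unlike CH.
* **Growing degree hours (GDH)** — the asymmetric curvilinear (ASYMCUR) heat
  response between a base, optimal and critical temperature: half-cosine rise
  from base to optimum, quarter-cosine fall from optimum to critical, zero
  outside.

All models return a :class:`ThermalAccumulation` aligned hour-by-hour to the
input series, supporting interval and calendar-window queries.  Intervals are
half-open ``(start, end]`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

__all__ = [
    "HourlyTemperatureSeries",
    "ThermalAccumulation",
    "DynamicModelParams",
    "GDHParams",
    "chilling_hours",
    "chill_portions",
    "growing_degree_hours",
    "accumulate_between",
    "windowed_chill_sum",
    "mean_daily_temperature",
]

HOUR = timedelta(hours=1)


class ThermalModelError(ValueError):
    """Raised for invalid series, parameters, or out-of-span queries."""


@dataclass(frozen=True)
class HourlyTemperatureSeries:
    """A strictly hourly, gap-free air-temperature series.

    Parameters
    ----------
    timestamps
        Strictly increasing hourly instants (timezone-naive local time).
    temp_c
        Air temperature per hour in degrees Celsius; finite values only.
    """

    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        temps = np.asarray(self.temp_c, dtype=float)
        if len(ts) == 0:
            raise ThermalModelError("empty temperature series: no data")
        if len(ts) != len(temps):
            raise ThermalModelError("timestamps and temperatures differ in length")
        if len(ts) > 1:
            steps = np.diff(ts.asi8)
            if not np.all(steps == 3_600_000_000_000):
                bad = int(np.argmax(steps != 3_600_000_000_000))
                raise ThermalModelError(
                    f"series is not strictly hourly at {ts[bad]} -> {ts[bad + 1]}"
                )
        if not np.all(np.isfinite(temps)):
            raise ThermalModelError("non-finite temperature values in series")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "temp_c", temps)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def start(self) -> pd.Timestamp:
        return self.timestamps[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.timestamps[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_c": self.temp_c})

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, max_gap_hours: int = 6, permissive: bool = False
    ) -> "HourlyTemperatureSeries":
        """Build a validated series from a ``timestamp,temp_c`` frame.

        Rows are sorted; gaps of at most ``max_gap_hours`` missing hours are
        filled by linear interpolation.  Longer gaps raise unless
        ``permissive`` is set, in which case they too are interpolated.
        """
        if frame.empty:
            raise ThermalModelError("empty temperature series: no data")
        df = frame[["timestamp", "temp_c"]].copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.sort_values("timestamp")
        dup = df["timestamp"].duplicated()
        if dup.any():
            first = df.loc[dup, "timestamp"].iloc[0]
            raise ThermalModelError(f"duplicate timestamp {first}")
        full = pd.date_range(df["timestamp"].iloc[0], df["timestamp"].iloc[-1], freq="h")
        s = df.set_index("timestamp")["temp_c"].reindex(full)
        if s.isna().any():
            gap_run = _longest_nan_run(s.to_numpy())
            if gap_run > max_gap_hours and not permissive:
                raise ThermalModelError(
                    f"temperature gap of {gap_run} h exceeds the "
                    f"{max_gap_hours} h interpolation limit"
                )
            s = s.interpolate(method="linear", limit_direction="both")
        return cls(timestamps=full, temp_c=s.to_numpy())


def _longest_nan_run(values: np.ndarray) -> int:
    isna = np.isnan(values)
    longest = run = 0
    for flag in isna:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return longest


@dataclass(frozen=True)
class ThermalAccumulation:
    """Hour-by-hour incremental and cumulative units of one thermal model."""

    model: str  # one of {"CH", "CP", "GDH"}
    timestamps: pd.DatetimeIndex
    incremental: np.ndarray
    cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        inc = np.asarray(self.incremental, dtype=float)
        if np.any(inc < 0):
            raise ThermalModelError("negative incremental accumulation")
        cum = np.cumsum(inc)
        object.__setattr__(self, "incremental", inc)
        object.__setattr__(self, "cumulative", cum)

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "model": self.model,
                "incremental": self.incremental,
                "cumulative": self.cumulative,
            }
        )


@dataclass(frozen=True)
class DynamicModelParams:
    """Kinetic constants of the two-step dynamic chill model.

    Defaults are the canonical published parameterization used by standard
    implementations; temperatures enter the kinetics in Kelvin.
    """

    slp: float = 1.6
    tetmlt: float = 277.0
    a0: float = 139500.0
    a1: float = 2.567e18
    e0: float = 4153.5
    e1: float = 12888.8

    def __post_init__(self) -> None:
        for name in ("slp", "tetmlt", "a0", "a1", "e0", "e1"):
            if not getattr(self, name) > 0:
                raise ThermalModelError(f"dynamic-model constant {name} must be > 0")


@dataclass(frozen=True)
class GDHParams:
    """ASYMCUR growing-degree-hour parameters (degC) and stress factor."""

    t_base: float = 4.0
    t_optimal: float = 25.0
    t_critical: float = 36.0
    stress_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_base < self.t_optimal < self.t_critical:
            raise ThermalModelError(
                "GDH temperatures must satisfy t_base < t_optimal < t_critical"
            )
        if not 0 < self.stress_factor <= 1:
            raise ThermalModelError("stress_factor must lie in (0, 1]")


def chilling_hours(
    series: HourlyTemperatureSeries, low: float = 0.0, high: float = 7.2
) -> ThermalAccumulation:
    """Count chill hours: one unit per hour with ``low < T <= high``.

    The band is open at ``low`` and closed at ``high`` (Weinberger
    convention); both boundaries are configurable.
    """
    if not low < high:
        raise ThermalModelError("chilling band requires low < high")
    inc = ((series.temp_c > low) & (series.temp_c <= high)).astype(float)
    return ThermalAccumulation("CH", series.timestamps, inc)


def chill_portions(
    series: HourlyTemperatureSeries, params: DynamicModelParams | None = None
) -> ThermalAccumulation:
    """Accumulate chill portions with the two-step dynamic model.

    Per hour at absolute temperature ``TK``:

    * equilibrium of the intermediate  ``xs = (a0/a1) * exp((e1 - e0)/TK)``
    * first-order rate toward it       ``ak1 = a1 * exp(-e1/TK)``
    * completion partition             ``xi = sr/(1 + sr)`` with
      ``sr = exp(slp * tetmlt * (TK - tetmlt)/TK)``

    The intermediate starts at 0.  Each hour it relaxes
    ``x_new = xs - (xs - x_carry) * exp(-ak1)``; when ``x_new >= 1`` the
    fraction ``xi * x_new`` is banked as chill portions and
    ``(1 - xi) * x_new`` carries into the next hour.
    """
    p = params or DynamicModelParams()
    tk = series.temp_c + 273.0
    sr = np.exp(p.slp * p.tetmlt * (tk - p.tetmlt) / tk)
    xi = sr / (1.0 + sr)
    xs = (p.a0 / p.a1) * np.exp((p.e1 - p.e0) / tk)
    decay = np.exp(-p.a1 * np.exp(-p.e1 / tk))

    n = len(series)
    inc = np.zeros(n)
    carry = 0.0
    for i in range(n):
        x = xs[i] - (xs[i] - carry) * decay[i]
        if x >= 1.0:
            inc[i] = xi[i] * x
            carry = x - inc[i]
        else:
            carry = x
    return ThermalAccumulation("CP", series.timestamps, inc)


def _gdh_response(temp_c: np.ndarray, p: GDHParams) -> np.ndarray:
    t = np.asarray(temp_c, dtype=float)
    span_rise = p.t_optimal - p.t_base
    span_fall = p.t_critical - p.t_optimal
    out = np.zeros_like(t)
    rise = (t >= p.t_base) & (t <= p.t_optimal)
    out[rise] = (span_rise / 2.0) * (
        1.0 + np.cos(np.pi + np.pi * (t[rise] - p.t_base) / span_rise)
    )
    fall = (t > p.t_optimal) & (t <= p.t_critical)
    out[fall] = span_rise * (
        1.0 + np.cos(np.pi / 2.0 + (np.pi / 2.0) * (t[fall] - p.t_optimal) / span_fall)
    )
    return p.stress_factor * out


def growing_degree_hours(
    series: HourlyTemperatureSeries, params: GDHParams | None = None
) -> ThermalAccumulation:
    """Accumulate ASYMCUR growing degree hours.

    Zero below base and above critical; half-cosine rise from 0 at base to
    ``t_optimal - t_base`` at the optimum; quarter-cosine fall back to 0 at
    the critical temperature; multiplied by the stress factor.
    """
    p = params or GDHParams()
    return ThermalAccumulation("GDH", series.timestamps, _gdh_response(series.temp_c, p))


def _as_timestamp(instant) -> pd.Timestamp:
    ts = pd.Timestamp(instant)
    return ts


def accumulate_between(acc: ThermalAccumulation, start, end) -> float:
    """Sum incremental units for hours with ``start < timestamp <= end``.

    Additive over adjacent intervals: the sum over ``(a, b]`` plus the sum
    over ``(b, c]`` equals the sum over ``(a, c]``.
    """
    start_ts, end_ts = _as_timestamp(start), _as_timestamp(end)
    if start_ts > end_ts:
        raise ThermalModelError("interval start is after interval end")
    if end_ts < acc.timestamps[0] or start_ts > acc.timestamps[-1]:
        raise ThermalModelError("interval lies outside the series span")
    mask = (acc.timestamps > start_ts) & (acc.timestamps <= end_ts)
    return float(acc.incremental[mask].sum())


def windowed_chill_sum(
    acc: ThermalAccumulation, date: Date | str, window_days: int = 14
) -> float:
    """Units accrued in the ``window_days`` ending with the given calendar day.

    The window is ``(end - window_days, end]`` with ``end`` the last hour of
    the given day.  Raises if the window lies fully outside the series span.
    """
    if window_days < 1:
        raise ThermalModelError("window_days must be >= 1")
    day = pd.Timestamp(date).normalize()
    end = day + timedelta(hours=23)
    start = end - timedelta(days=window_days)
    if end < acc.timestamps[0] or start >= acc.timestamps[-1]:
        raise ThermalModelError(f"window ending {day.date()} lies outside the series")
    return accumulate_between(acc, max(start, acc.timestamps[0] - HOUR), end)


def mean_daily_temperature(
    series: HourlyTemperatureSeries, date: Date | str, min_hours: int = 20
) -> float:
    """Arithmetic mean of one calendar day's hourly temperatures.

    Requires at least ``min_hours`` of the 24 hours to be present (default
    20) so sparse boundary days are not silently averaged.
    """
    day = pd.Timestamp(date).normalize()
    mask = (series.timestamps >= day) & (series.timestamps < day + timedelta(days=1))
    n = int(mask.sum())
    if n == 0:
        raise ThermalModelError(f"day {day.date()} absent from series")
    if n < min_hours:
        raise ThermalModelError(
            f"day {day.date()} has only {n} of 24 hours (minimum {min_hours})"
        )
    return float(series.temp_c[mask].mean())
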