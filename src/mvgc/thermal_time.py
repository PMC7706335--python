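"""Thermal time: growing degree days (GDD) and GS30-anchored offsets.

Wheat phenology is driven by accumulated temperature rather than calendar
time.  Hourly air temperature is aggregated into growing degree days

    GDD(DAS) = sum_{d=1..DAS} sum_{h=1..24} max(T_{d,h} - T_base, 0) / 24

with ``T_base`` defaulting to 0 °C for winter wheat.  Each plot additionally
carries a thermal-time anchor ``GDD_GS30`` — the cumulative GDD at which stem
elongation begins — so that trait trajectories of genotypes with different
earliness can be compared on a common axis ``ΔGDD_GS30 = GDD − GDD_GS30``
(negative before, positive after the beginning of stem elongation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "GddSeries",
    "Gs30Anchor",
    "compute_gdd",
    "delta_gdd",
    "read_temperature_csv",
]

#: coldest physically plausible base temperature accepted, °C
_T_BASE_FLOOR = -50.0


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly air-temperature record starting at sowing.

    Parameters
    ----------
    timestamps
        Hourly instants (``pandas.DatetimeIndex`` or convertible), strictly
        increasing, interpreted in local civil time of the site.
    t_h
        Air temperature per hour, °C.
    sowing_date
        Calendar date of sowing; day 1 of the DAS axis is the first full day
        after sowing.
    """

    timestamps: pd.DatetimeIndex
    t_h: np.ndarray
    sowing_date: pd.Timestamp

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        t = np.asarray(self.t_h, dtype=float)
        if len(ts) != len(t):
            raise ValueError("timestamps and t_h must have equal length")
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(ts) and ts.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "t_h", t)
        object.__setattr__(self, "sowing_date", pd.Timestamp(self.sowing_date).normalize())

    @property
    def missing_days(self) -> list[pd.Timestamp]:
        """Days after sowing with fewer than 24 hourly records (flagged, never filled)."""
        if not len(self.timestamps):
            return []
        days = pd.Series(1, index=self.timestamps).resample("D").count()
        days = days[days.index > self.sowing_date]
        return [d for d, n in days.items() if n < 24]


@dataclass(frozen=True)
class GddSeries:
    """Cumulative growing degree days on an integer days-after-sowing axis."""

    das: np.ndarray
    gdd: np.ndarray
    t_base: float = 0.0

    def __post_init__(self) -> None:
        das = np.asarray(self.das, dtype=int)
        gdd = np.asarray(self.gdd, dtype=float)
        if das.shape != gdd.shape:
            raise ValueError("das and gdd must have equal shape")
        if len(gdd):
            if gdd[0] < 0:
                raise ValueError("gdd must start at a nonnegative value")
            if np.any(np.diff(gdd) < -1e-12):
                raise ValueError("gdd must be nondecreasing in das")
        object.__setattr__(self, "das", das)
        object.__setattr__(self, "gdd", gdd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"das": self.das, "gdd": self.gdd})

    def at_das(self, das: int) -> float:
        idx = np.searchsorted(self.das, das)
        if idx >= len(self.das) or self.das[idx] != das:
            raise KeyError(f"day {das} not in series")
        return float(self.gdd[idx])


@dataclass(frozen=True)
class Gs30Anchor:
    """Per-plot thermal-time anchor: cumulative GDD at beginning of stem elongation."""

    gdd_gs30: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gdd_gs30) or self.gdd_gs30 <= 0:
            raise ValueError("gdd_gs30 must be finite and > 0")


def compute_gdd(temps: TemperatureSeries, t_base: float = 0.0) -> GddSeries:
    """Accumulate hourly temperatures into a cumulative GDD series.

    Every full day after sowing contributes ``Σ_h max(T_h − t_base, 0) / 24``
    °C·day.  Days with fewer than 24 hourly records are rejected: the daily
    divisor is exactly 24, so scaling a partial day would silently change the
    quantity being accumulated.

    Parameters
    ----------
    temps
        Hourly temperature record.
    t_base
        Base temperature in °C below which no thermal time accrues
        (default 0 °C for winter wheat).

    Returns
    -------
    GddSeries
        Cumulative GDD per integer day after sowing.
    """
    if t_base < _T_BASE_FLOOR:
        raise ValueError(f"t_base {t_base} °C below plausible floor {_T_BASE_FLOOR} °C")
    missing = temps.missing_days
    if missing:
        days = ", ".join(str(d.date()) for d in missing[:5])
        raise ValueError(f"days with fewer than 24 hourly records: {days}")

    contrib = np.maximum(temps.t_h - t_base, 0.0) / 24.0
    daily = pd.Series(contrib, index=temps.timestamps).resample("D").sum()
    daily = daily[daily.index > temps.sowing_date]
    if daily.empty:
        raise ValueError("no complete days after sowing in temperature record")
    das = ((daily.index - temps.sowing_date) / pd.Timedelta(days=1)).astype(int)
    return GddSeries(das=np.asarray(das), gdd=np.cumsum(daily.to_numpy()), t_base=t_base)


def delta_gdd(gdd, anchor: Gs30Anchor):
    """Thermal time relative to the GS30 anchor: ``ΔGDD_GS30 = GDD − GDD_GS30``.

    Accepts a :class:`GddSeries` (returns an array aligned to its ``das``
    axis), an array, or a scalar.  Negative values precede the beginning of
    stem elongation, positive values follow it.
    """
    if isinstance(gdd, GddSeries):
        return gdd.gdd - anchor.gdd_gs30
    return np.asarray(gdd, dtype=float) - anchor.gdd_gs30


def read_temperature_csv(path, sowing_date) -> TemperatureSeries:
    """Read an hourly temperature CSV with columns ``timestamp`` (ISO-8601), ``temp_c``."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "temp_c" not in df.columns:
        raise ValueError("temperature CSV must have columns timestamp, temp_c")
    return TemperatureSeries(
        timestamps=pd.DatetimeIndex(df["timestamp"]),
        t_h=df["temp_c"].to_numpy(dtype=float),
        sowing_date=sowing_date,
    )
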