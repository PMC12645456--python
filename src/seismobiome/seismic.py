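"""Earthquake-catalog kinetic energy absorbed at a borehole receiver.

The chain implemented here converts a local-magnitude earthquake catalog
into per-event radiated energy (Richter relation ``log10 J = 4.4 + 1.5 M``),
attenuates it to a receiver with an inverse-square law over the slant
(hypocentral-to-sampling-point) distance, and accumulates the absorbed
energy — and, with the same machinery, precipitation — over the half-open
windows defined by a sampling schedule.

Distances: the epicentre-to-wellhead surface distance is a Vincenty
geodesic on WGS-84; the slant distance adds the vertical separation between
the hypocentre (km below sea level) and the sampled depth (wellhead
elevation minus sampling depth, above sea level) by the Pythagorean
theorem.

Units: radiated energy is in joules; "absorbed" energy is J / D^2 with D in
km. The implicit km^-2 is conventionally dropped so absorbed values are
reported in J (or kJ / MJ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._geodesy import vincenty_km

__all__ = [
    "SeismicEvent",
    "ReceiverSite",
    "EventEnergy",
    "SamplingSchedule",
    "WindowAccumulation",
    "B944_SITE",
    "PAPER_SCHEDULE",
    "magnitude_to_energy",
    "surface_distance",
    "slant_distance",
    "absorbed_energy",
    "catalog_energies",
    "build_windows",
    "accumulate",
]

# Richter energy relation: log10(J) = RICHTER_INTERCEPT + RICHTER_SLOPE * M
RICHTER_INTERCEPT = 4.4
RICHTER_SLOPE = 1.5


@dataclass(frozen=True)
class SeismicEvent:
    """One catalog row: origin time (Julian day-of-year), epicentre, depth, magnitude."""

    day: float  # Julian day-of-year (fractional for intra-day time)
    lat: float
    lon: float
    depth_bsl: float  # km below sea level; slightly negative allowed
    magnitude: float

    def __post_init__(self):
        if not math.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError("invalid epicentre coordinates")
        if self.depth_bsl < -10:
            raise ValueError("depth below -10 km above sea level is not physical here")


@dataclass(frozen=True)
class ReceiverSite:
    """Borehole receiver: wellhead location, elevation (m asl), sampling depth (m below wellhead)."""

    lat: float
    lon: float
    elevation: float
    sampling_depth: float

    def __post_init__(self):
        if self.sampling_depth < 0:
            raise ValueError("sampling_depth must be >= 0")

    @property
    def sampled_elevation_km(self) -> float:
        """Elevation of the sampled point above sea level, km."""
        return (self.elevation - self.sampling_depth) / 1000.0


@dataclass(frozen=True)
class EventEnergy:
    event: SeismicEvent
    radiated_J: float
    distance_km: float
    absorbed: float  # J / km^2, reported as J (see module docstring)


#: Grant B944 borehole, Yellowstone National Park (wellhead 2365 m asl, sampled at 99.1 m).
B944_SITE = ReceiverSite(lat=44.389669, lon=-110.543722, elevation=2365.0, sampling_depth=99.1)

#: 2021 sampling schedule, Julian days (May 27, Jun 23, Aug 25, Oct 6, Nov 3).
PAPER_SCHEDULE = (147, 174, 237, 279, 307)


def magnitude_to_energy(magnitude):
    """Radiated energy (J) from local Richter magnitude, log10 J = 4.4 + 1.5 M.

    Accepts scalars or arrays; strictly increasing in M (a 2-unit magnitude
    step is a 1000-fold energy step).
    """
    m = np.asarray(magnitude, dtype=float)
    if np.any(~np.isfinite(m)):
        raise ValueError("magnitude must be finite")
    out = 10.0 ** (RICHTER_INTERCEPT + RICHTER_SLOPE * m)
    return float(out) if np.ndim(magnitude) == 0 else out


def surface_distance(lat1, lon1, lat2, lon2):
    """WGS-84 geodesic (Vincenty) surface distance in km; symmetric, 0 iff identical."""
    return vincenty_km(lat1, lon1, lat2, lon2)


def slant_distance(surface_km, event_depth_bsl, receiver: ReceiverSite):
    """Hypocentre-to-sampling-point distance, km.

    The vertical separation is ``depth_bsl + (elevation - sampling_depth)/1000``:
    the hypocentre sits ``depth_bsl`` km below sea level and the sampled point
    ``(elevation - sampling_depth)`` m above it.
    """
    s = np.asarray(surface_km, dtype=float)
    if np.any(s < 0):
        raise ValueError("surface distance must be >= 0")
    dv = np.asarray(event_depth_bsl, dtype=float) + receiver.sampled_elevation_km
    out = np.hypot(s, dv)
    return float(out) if np.ndim(surface_km) == 0 and np.ndim(event_depth_bsl) == 0 else out


def absorbed_energy(event: SeismicEvent, receiver: ReceiverSite) -> EventEnergy:
    """Distance-attenuated energy for one event: J(M) / D^2 with D the slant km."""
    radiated = magnitude_to_energy(event.magnitude)
    surf = surface_distance(event.lat, event.lon, receiver.lat, receiver.lon)
    dist = slant_distance(surf, event.depth_bsl, receiver)
    if dist == 0:
        raise ValueError("event coincides with the receiver; absorbed energy undefined")
    return EventEnergy(event=event, radiated_J=radiated, distance_km=dist, absorbed=radiated / dist**2)


def catalog_energies(catalog: pd.DataFrame, receiver: ReceiverSite) -> pd.DataFrame:
    """Vectorised per-event energies for a catalog DataFrame.

    Expects columns ``day, lat, lon, depth_km, magnitude``; rows with missing
    magnitude are dropped (count returned in ``df.attrs['n_dropped']``).
    Returns a copy with ``radiated_J``, ``distance_km`` and ``absorbed_J``
    columns appended.
    """
    required = {"day", "lat", "lon", "depth_km", "magnitude"}
    missing = required - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    df = catalog.copy()
    bad = ~np.isfinite(pd.to_numeric(df["magnitude"], errors="coerce"))
    n_dropped = int(bad.sum())
    df = df.loc[~bad].copy()
    df["magnitude"] = df["magnitude"].astype(float)
    df["radiated_J"] = magnitude_to_energy(df["magnitude"].to_numpy())
    surf = surface_distance(
        df["lat"].to_numpy(), df["lon"].to_numpy(), receiver.lat, receiver.lon
    )
    dist = slant_distance(surf, df["depth_km"].to_numpy(), receiver)
    if np.any(dist == 0):
        raise ValueError("event coincides with the receiver; absorbed energy undefined")
    df["distance_km"] = dist
    df["absorbed_J"] = df["radiated_J"] / dist**2
    df.attrs["n_dropped"] = n_dropped
    return df


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered Julian day-of-year sampling dates within one calendar year."""

    days: tuple = PAPER_SCHEDULE

    def __post_init__(self):
        days = tuple(int(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if len(days) < 2:
            raise ValueError("schedule needs at least 2 sampling days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling days must be strictly increasing")
        if days[0] < 1 or days[-1] > 366:
            raise ValueError("sampling days must lie within one calendar year (1..366)")

    @property
    def mean_interval(self) -> float:
        """Mean of all consecutive inter-sampling intervals, days."""
        d = np.diff(self.days)
        return float(d.mean())


@dataclass(frozen=True)
class WindowAccumulation:
    window_start_day: float
    window_end_day: float
    total: float
    n_events: int

    def __post_init__(self):
        if self.window_end_day <= self.window_start_day:
            raise ValueError("window must have positive length")


def build_windows(schedule: SamplingSchedule) -> list[tuple[float, float]]:
    """Half-open accumulation windows ``(start, end]``, one per sampling date.

    The first window extends back from the first sampling date by the rounded
    mean consecutive inter-sampling interval (40 days for the 2021 schedule,
    i.e. a first window of (107, 147]); each later window spans consecutive
    sampling dates. Windows tile the schedule without overlap.
    """
    days = schedule.days
    lookback = round(schedule.mean_interval)
    windows = [(days[0] - lookback, days[0])]
    windows += [(a, b) for a, b in zip(days, days[1:])]
    return windows


def accumulate(days, values, windows) -> tuple[list[WindowAccumulation], dict]:
    """Sum timestamped values over half-open windows ``(start, end]``.

    Works for per-event absorbed energies and for daily precipitation alike.
    Returns the per-window accumulations and a diagnostics dict with the
    number and total of values falling outside every window.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ValueError("days and values must have the same length")
    out = []
    in_any = np.zeros(days.shape, dtype=bool)
    for start, end in windows:
        mask = (days > start) & (days <= end)
        in_any |= mask
        out.append(
            WindowAccumulation(
                window_start_day=start,
                window_end_day=end,
                total=float(values[mask].sum()),
                n_events=int(mask.sum()),
            )
        )
    diagnostics = {
        "n_outside": int((~in_any).sum()),
        "total_outside": float(values[~in_any].sum()),
    }
    return out, diagnostics


def windows_frame(accs: Iterable[WindowAccumulation]) -> pd.DataFrame:
    """Tabulate WindowAccumulation records."""
    return pd.DataFrame(
        [
            {
                "window_start_day": a.window_start_day,
                "window_end_day": a.window_end_day,
                "total": a.total,
                "n_events": a.n_events,
            }
            for a in accs
        ]
    )
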