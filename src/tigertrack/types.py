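"""Typed records for every file the pipeline touches.

These are deliberately light dataclasses rather than a DataFrame-first API:
each record type carries the validation rules of its file format, and the
readers in :mod:`tigertrack.io` promote raw CSV rows into these types (or
reject them with a reason).  DataFrames are used internally where vectorised
work pays off.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: the three acoustic tag configurations used in the study:
#: estimated battery life (days) -> (min, max) transmission delay (s)
TAG_CONFIGS = {696: (50, 130), 835: (40, 80), 1448: (30, 90)}

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")


class ValidationError(ValueError):
    """A record violates a hard invariant of its type."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Receiver:
    """One moored acoustic receiver with its deployment interval."""

    receiver_id: str
    array_name: str
    lon: float
    lat: float
    mooring_depth_m: float
    deployed_from: pd.Timestamp
    deployed_to: pd.Timestamp

    def __post_init__(self):
        _check(-180.0 <= self.lon <= 180.0, "longitude out of range")
        _check(-90.0 <= self.lat <= 90.0, "latitude out of range")
        _check(self.mooring_depth_m >= 0, "mooring depth negative")
        _check(self.deployed_from < self.deployed_to,
               "deployment interval empty or inverted")


@dataclass(frozen=True)
class Detection:
    """A single acoustic detection event: tag heard by a receiver."""

    tag_id: str
    receiver_id: str
    timestamp: pd.Timestamp


@dataclass(frozen=True)
class TagDeployment:
    """Acoustic tag + shark metadata defining one monitoring history."""

    tag_id: str
    shark_id: str
    sex: str
    total_length_cm: float
    maturity: str
    clasper_state: str
    release_time: pd.Timestamp
    release_lon: float
    release_lat: float
    battery_days: int
    delay_s: tuple[int, int]

    def __post_init__(self):
        _check(self.sex in ("M", "F"), "sex must be M or F")
        _check(50.0 < self.total_length_cm < 600.0, "total length out of range")
        _check(self.maturity in ("juvenile", "sub_adult", "mature"),
               "unknown maturity class")
        _check(self.clasper_state in
               ("none", "semi_calcified", "calcified", "not_applicable"),
               "unknown clasper state")
        _check(-180.0 <= self.release_lon <= 180.0, "longitude out of range")
        _check(-90.0 <= self.release_lat <= 90.0, "latitude out of range")
        _check(self.battery_days in TAG_CONFIGS, "unknown tag battery configuration")
        _check(tuple(self.delay_s) == TAG_CONFIGS[self.battery_days],
               "delay range does not match battery configuration")


@dataclass(frozen=True)
class ArgosPosition:
    """One satellite fix with its Argos location class (Z: no coordinates)."""

    tag_id: str
    timestamp: pd.Timestamp
    loc_class: str
    lon: Optional[float] = None
    lat: Optional[float] = None

    def __post_init__(self):
        _check(self.loc_class in ARGOS_CLASSES, "unknown Argos location class")
        if self.loc_class == "Z":
            _check(self.lon is None and self.lat is None,
                   "class Z fixes carry no coordinates")
        else:
            _check(self.lon is not None and self.lat is not None,
                   "non-Z fix requires coordinates")
            _check(-180.0 <= self.lon <= 180.0, "longitude out of range")
            _check(-90.0 <= self.lat <= 90.0, "latitude out of range")


@dataclass(frozen=True)
class DepthTempRecord:
    """One archival depth-temperature sample from a PSAT."""

    tag_id: str
    timestamp: pd.Timestamp
    depth_m: float
    temp_c: float

    def __post_init__(self):
        _check(np.isfinite(self.depth_m) and self.depth_m >= 0.0,
               "depth must be finite and non-negative")
        _check(-5.0 < self.temp_c < 45.0, "temperature out of plausible range")


@dataclass(frozen=True)
class TrackPoint:
    """One day of a most-probable geolocated track."""

    tag_id: str
    date: pd.Timestamp  # calendar day
    lon: float
    lat: float
    ci_radius_km: Optional[float] = None
    max_daily_depth_m: Optional[float] = None

    def __post_init__(self):
        _check(-180.0 <= self.lon <= 180.0, "longitude out of range")
        _check(-90.0 <= self.lat <= 90.0, "latitude out of range")
        if self.ci_radius_km is not None:
            _check(self.ci_radius_km >= 0, "CI radius negative")
        if self.max_daily_depth_m is not None:
            _check(self.max_daily_depth_m >= 0, "max daily depth negative")


@dataclass
class BathymetryGrid:
    """Regular lon/lat grid of positive seafloor depths (metres)."""

    lon: np.ndarray  # shape (nx,), strictly increasing degrees
    lat: np.ndarray  # shape (ny,), strictly increasing degrees
    seafloor_depth_m: np.ndarray  # shape (ny, nx), > 0

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.seafloor_depth_m = np.asarray(self.seafloor_depth_m, dtype=float)
        _check(np.all(np.diff(self.lon) > 0), "lon axis not strictly increasing")
        _check(np.all(np.diff(self.lat) > 0), "lat axis not strictly increasing")
        _check(self.seafloor_depth_m.shape == (self.lat.size, self.lon.size),
               "depth array shape does not match axes")
        _check(np.all(np.isfinite(self.seafloor_depth_m)), "non-finite depths")
        _check(np.all(self.seafloor_depth_m > 0), "seafloor depths must be positive")

    def depth_at(self, lon, lat):
        """Seafloor depth of the cell nearest each query point (nearest-cell lookup)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.clip(np.searchsorted(self.lon, lon), 1, self.lon.size - 1)
        i = np.where(np.abs(lon - self.lon[i - 1]) <= np.abs(self.lon[i] - lon), i - 1, i)
        j = np.clip(np.searchsorted(self.lat, lat), 1, self.lat.size - 1)
        j = np.where(np.abs(lat - self.lat[j - 1]) <= np.abs(self.lat[j] - lat), j - 1, j)
        return self.seafloor_depth_m[j, i]

    def covers(self, lon, lat) -> bool:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return bool(np.all((lon >= self.lon[0]) & (lon <= self.lon[-1])
                           & (lat >= self.lat[0]) & (lat <= self.lat[-1])))


@dataclass
class ValidationReport:
    """Per-file account of rejected rows: (row number, reason)."""

    source: str = ""
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __bool__(self) -> bool:  # truthy when clean
        return not self.rejected
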