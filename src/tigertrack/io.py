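"""CSV readers and writers for every pipeline file format.

Dialects are plain comma-separated files with ISO-8601 UTC timestamps and the
documented headers below.  Every reader returns ``(records, report)``: typed,
time-sorted records plus a :class:`~tigertrack.types.ValidationReport` listing
rejected rows with reasons.  Rows that violate a field invariant are rejected,
not fatal; a malformed header is fatal.  Write-then-read is the identity on
all record types.

Headers
-------
- ``detections.csv``: tag_id,receiver_id,timestamp
- ``receivers.csv``: receiver_id,array_name,lon,lat,mooring_depth_m,deployed_from,deployed_to
- ``tags.csv``: tag_id,shark_id,sex,total_length_cm,maturity,clasper_state,release_time,release_lon,release_lat,battery_days,delay_min_s,delay_max_s
- ``argos.csv``: tag_id,timestamp,loc_class,lon,lat  (lon/lat empty for class Z)
- ``depth_series.csv``: tag_id,timestamp,depth_m,temp_c
- ``track.csv``: tag_id,date,lon,lat,ci_radius_km,max_daily_depth_m
- ``bathymetry.csv``: lon,lat,seafloor_depth_m  (long-format regular grid)
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .types import (ArgosPosition, BathymetryGrid, Detection, DepthTempRecord,
                    Receiver, TagDeployment, TrackPoint, ValidationError,
                    ValidationReport)

log = logging.getLogger("tigertrack")

HEADERS = {
    "detections": ["tag_id", "receiver_id", "timestamp"],
    "receivers": ["receiver_id", "array_name", "lon", "lat", "mooring_depth_m",
                  "deployed_from", "deployed_to"],
    "tags": ["tag_id", "shark_id", "sex", "total_length_cm", "maturity",
             "clasper_state", "release_time", "release_lon", "release_lat",
             "battery_days", "delay_min_s", "delay_max_s"],
    "argos": ["tag_id", "timestamp", "loc_class", "lon", "lat"],
    "depth_series": ["tag_id", "timestamp", "depth_m", "temp_c"],
    "track": ["tag_id", "date", "lon", "lat", "ci_radius_km", "max_daily_depth_m"],
    "bathymetry": ["lon", "lat", "seafloor_depth_m"],
}


class ParseError(ValueError):
    """File-level failure: missing file, wrong header, unreadable timestamps."""


def _load(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{kind} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = HEADERS[kind]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected header {','.join(expected)}, "
                         f"got {','.join(df.columns)}")
    return df

def _ts(value: str) -> pd.Timestamp:
    t = pd.Timestamp(value)
    if pd.isna(t):
        raise ValidationError("unparseable timestamp")
    return t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")


def _rows_to_records(df: pd.DataFrame, build: Callable, report: ValidationReport):
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(build(row))
        except (ValidationError, ValueError) as exc:
            report.reject(idx, str(exc))
    return records


def read_detections(path) -> tuple[list[Detection], ValidationReport]:
    df = _load(path, "detections")
    report = ValidationReport(str(path))
    recs = _rows_to_records(
        df, lambda r: Detection(r.tag_id, r.receiver_id, _ts(r.timestamp)), report)
    recs.sort(key=lambda d: (d.timestamp, d.tag_id, d.receiver_id))
    return recs, report


def validate_detection_windows(detections: list[Detection],
                               receivers: list[Receiver]) -> ValidationReport:
    """Report detections falling outside their receiver's deployment interval."""
    by_id = {r.receiver_id: r for r in receivers}
    report = ValidationReport("detection/deployment cross-check")
    for i, d in enumerate(detections):
        rec = by_id.get(d.receiver_id)
        if rec is None:
            report.reject(i, f"unknown receiver {d.receiver_id}")
        elif not (rec.deployed_from <= d.timestamp <= rec.deployed_to):
            report.reject(i, f"detection outside deployment of {d.receiver_id}")
    return report


def read_receivers(path) -> tuple[list[Receiver], ValidationReport]:
    df = _load(path, "receivers")
    report = ValidationReport(str(path))
    recs = _rows_to_records(
        df,
        lambda r: Receiver(r.receiver_id, r.array_name, float(r.lon), float(r.lat),
                           float(r.mooring_depth_m), _ts(r.deployed_from),
                           _ts(r.deployed_to)),
        report)
    recs.sort(key=lambda r: r.receiver_id)
    return recs, report


def read_tags(path) -> tuple[list[TagDeployment], ValidationReport]:
    df = _load(path, "tags")
    report = ValidationReport(str(path))
    recs = _rows_to_records(
        df,
        lambda r: TagDeployment(r.tag_id, r.shark_id, r.sex, float(r.total_length_cm),
                                r.maturity, r.clasper_state, _ts(r.release_time),
                                float(r.release_lon), float(r.release_lat),
                                int(r.battery_days),
                                (int(r.delay_min_s), int(r.delay_max_s))),
        report)
    recs.sort(key=lambda t: (t.release_time, t.tag_id))
    return recs, report


def read_argos(path) -> tuple[list[ArgosPosition], ValidationReport]:
    df = _load(path, "argos")
    report = ValidationReport(str(path))

    def build(r):
        if r.loc_class == "Z":
            if r.lon or r.lat:
                raise ValidationError("class Z fixes carry no coordinates")
            return ArgosPosition(r.tag_id, _ts(r.timestamp), "Z")
        return ArgosPosition(r.tag_id, _ts(r.timestamp), r.loc_class,
                             float(r.lon), float(r.lat))

    recs = _rows_to_records(df, build, report)
    recs.sort(key=lambda p: (p.tag_id, p.timestamp))
    return recs, report


def read_depth_series(path) -> tuple[list[DepthTempRecord], ValidationReport]:
    df = _load(path, "depth_series")
    report = ValidationReport(str(path))
    recs = _rows_to_records(
        df,
        lambda r: DepthTempRecord(r.tag_id, _ts(r.timestamp), float(r.depth_m),
                                  float(r.temp_c)),
        report)
    recs.sort(key=lambda d: (d.tag_id, d.timestamp))
    return recs, report


def read_track(path) -> tuple[list[TrackPoint], ValidationReport]:
    df = _load(path, "track")
    report = ValidationReport(str(path))

    def build(r):
        return TrackPoint(
            r.tag_id, _ts(r.date).normalize(), float(r.lon), float(r.lat),
            float(r.ci_radius_km) if r.ci_radius_km != "" else None,
            float(r.max_daily_depth_m) if r.max_daily_depth_m != "" else None)

    recs = _rows_to_records(df, build, report)
    recs.sort(key=lambda p: (p.tag_id, p.date))
    for a, b in zip(recs, recs[1:]):
        if a.tag_id == b.tag_id and a.date >= b.date:
            report.reject(-1, f"duplicate/non-increasing date for {b.tag_id}: {b.date.date()}")
    return recs, report


def read_bathymetry(path) -> BathymetryGrid:
    df = _load(path, "bathymetry")
    lon = np.sort(df["lon"].astype(float).unique())
    lat = np.sort(df["lat"].astype(float).unique())
    depth = (df.astype({"lon": float, "lat": float, "seafloor_depth_m": float})
             .pivot(index="lat", columns="lon", values="seafloor_depth_m")
             .reindex(index=lat, columns=lon))
    if depth.isna().any().any():
        raise ParseError(f"{path}: bathymetry grid is not complete/regular")
    return BathymetryGrid(lon, lat, depth.to_numpy())


# ---------------------------------------------------------------- writers

def _iso(t: pd.Timestamp) -> str:
    # full sub-second precision so write-then-read is the identity
    return t.tz_convert("UTC").isoformat().replace("+00:00", "Z")


def write_detections(detections: list[Detection], path) -> None:
    pd.DataFrame([{"tag_id": d.tag_id, "receiver_id": d.receiver_id,
                   "timestamp": _iso(d.timestamp)} for d in detections],
                 columns=HEADERS["detections"]).to_csv(path, index=False)


def write_receivers(receivers: list[Receiver], path) -> None:
    pd.DataFrame([{"receiver_id": r.receiver_id, "array_name": r.array_name,
                   "lon": r.lon, "lat": r.lat, "mooring_depth_m": r.mooring_depth_m,
                   "deployed_from": _iso(r.deployed_from),
                   "deployed_to": _iso(r.deployed_to)} for r in receivers],
                 columns=HEADERS["receivers"]).to_csv(path, index=False)


def write_tags(tags: list[TagDeployment], path) -> None:
    pd.DataFrame([{"tag_id": t.tag_id, "shark_id": t.shark_id, "sex": t.sex,
                   "total_length_cm": t.total_length_cm, "maturity": t.maturity,
                   "clasper_state": t.clasper_state,
                   "release_time": _iso(t.release_time),
                   "release_lon": t.release_lon, "release_lat": t.release_lat,
                   "battery_days": t.battery_days,
                   "delay_min_s": t.delay_s[0], "delay_max_s": t.delay_s[1]}
                  for t in tags], columns=HEADERS["tags"]).to_csv(path, index=False)


def write_argos(positions: list[ArgosPosition], path) -> None:
    pd.DataFrame([{"tag_id": p.tag_id, "timestamp": _iso(p.timestamp),
                   "loc_class": p.loc_class,
                   "lon": "" if p.lon is None else p.lon,
                   "lat": "" if p.lat is None else p.lat} for p in positions],
                 columns=HEADERS["argos"]).to_csv(path, index=False)


def write_depth_series(series: list[DepthTempRecord], path) -> None:
    pd.DataFrame([{"tag_id": d.tag_id, "timestamp": _iso(d.timestamp),
                   "depth_m": d.depth_m, "temp_c": d.temp_c} for d in series],
                 columns=HEADERS["depth_series"]).to_csv(path, index=False)


def write_track(track: list[TrackPoint], path) -> None:
    pd.DataFrame([{"tag_id": p.tag_id, "date": p.date.strftime("%Y-%m-%d"),
                   "lon": p.lon, "lat": p.lat,
                   "ci_radius_km": "" if p.ci_radius_km is None else p.ci_radius_km,
                   "max_daily_depth_m": ("" if p.max_daily_depth_m is None
                                         else p.max_daily_depth_m)}
                  for p in track], columns=HEADERS["track"]).to_csv(path, index=False)


def write_bathymetry(grid: BathymetryGrid, path) -> None:
    lon2, lat2 = np.meshgrid(grid.lon, grid.lat)
    pd.DataFrame({"lon": lon2.ravel(), "lat": lat2.ravel(),
                  "seafloor_depth_m": grid.seafloor_depth_m.ravel()}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Key-value run configuration shared by all stages (YAML on disk)."""

    utc_offset_hours: float = 11.0     # New Caledonia local clock
    vmax_kmh: float = 3.5              # plausibility speed for Argos filtering
    visit_gap_min: float = 30.0        # gap closing consecutive detections into a visit
    ri_threshold: float = 0.30         # residency-index boundary of the behaviour rules
    gap_days: int = 31                 # "one month" re-detection gap
    kud_grid_n: int = 64
    kud_mass_levels: tuple[float, ...] = (0.50, 0.95)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.kud_mass_levels = tuple(float(m) for m in cfg.kud_mass_levels)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["kud_mass_levels"] = list(self.kud_mass_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def to_local(ts: pd.Timestamp, utc_offset_hours: float) -> pd.Timestamp:
    """Map a UTC instant to the dataset's fixed-offset local wall clock."""
    return ts.tz_convert("UTC") + pd.Timedelta(hours=utc_offset_hours)
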