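"""Post-geolocation track utilities.

Covers the simplified bathymetric correction (a geolocated position cannot
sit over seafloor shallower than the shark's maximum dive of that day), the
maximum displacement from the release point, and the archival
depth-temperature summary statistics (max / mean / modal values, with modal
values as centres of fixed-width bins).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .geo import haversine_km
from .types import BathymetryGrid, DepthTempRecord, TrackPoint


@dataclass(frozen=True)
class CorrectedPoint:
    point: TrackPoint
    moved: bool
    infeasible: bool   # no valid cell within the search radius
    displacement_km: float


@dataclass(frozen=True)
class DepthTempSummary:
    tag_id: str
    max_depth_m: float
    modal_depth_m: float
    mean_depth_m: float
    max_temp_c: float
    min_temp_c: float
    modal_temp_c: float
    mean_temp_c: float
    depth_bin_m: float
    temp_bin_c: float


def bathymetric_correct(track: Sequence[TrackPoint], bathy: BathymetryGrid,
                        search_radius_km: float = 100.0) -> list[CorrectedPoint]:
    """Relocate track points over implausibly shallow seafloor.

    A point whose nearest-cell seafloor depth is less than its maximum daily
    dive depth moves to the nearest grid cell (great-circle) deep enough,
    searched within ``search_radius_km`` (capped by the point's CI radius
    when present).  Points with no feasible cell in range are flagged and
    left in place; points without a recorded daily depth are untouched.
    """
    if not all(bathy.covers(p.lon, p.lat) for p in track):
        raise ValueError("track extends outside the bathymetry grid")
    lon2, lat2 = np.meshgrid(bathy.lon, bathy.lat)
    out: list[CorrectedPoint] = []
    for p in track:
        need = p.max_daily_depth_m
        if need is None or need <= 0:
            out.append(CorrectedPoint(p, False, False, 0.0))
            continue
        here = float(bathy.depth_at(p.lon, p.lat))
        if here >= need:
            out.append(CorrectedPoint(p, False, False, 0.0))
            continue
        radius = search_radius_km
        if p.ci_radius_km is not None:
            radius = min(radius, p.ci_radius_km)
        dist = haversine_km(p.lon, p.lat, lon2, lat2)
        ok = (bathy.seafloor_depth_m >= need) & (dist <= radius)
        if not np.any(ok):
            out.append(CorrectedPoint(p, False, True, 0.0))
            continue
        masked = np.where(ok, dist, np.inf)
        j, i = np.unravel_index(int(np.argmin(masked)), masked.shape)
        moved = replace(p, lon=float(bathy.lon[i]), lat=float(bathy.lat[j]))
        out.append(CorrectedPoint(moved, True, False, float(dist[j, i])))
    return out


def corrected_track(corrections: Sequence[CorrectedPoint]) -> list[TrackPoint]:
    return [c.point for c in corrections]


def displacement_from_release(track: Sequence[TrackPoint],
                              release_point: tuple[float, float]) -> float:
    """Maximum great-circle distance (km) from release over the whole track."""
    if not track:
        raise ValueError("track is empty")
    lon = np.array([p.lon for p in track])
    lat = np.array([p.lat for p in track])
    return float(np.max(haversine_km(release_point[0], release_point[1], lon, lat)))


def _modal_bin_centre(values: np.ndarray, width: float) -> float:
    """Centre of the most populated fixed-width bin; ties break low.

    Bins are centred on multiples of the width (edges at k*width +/- width/2),
    so modal values land on the half-metre / tenth-degree grid the study's
    summary tables print.
    """
    idx = np.floor(values / width + 0.5).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    best = uniq[counts == counts.max()].min()
    return float(best * width)


def depth_temp_summary(series: Sequence[DepthTempRecord],
                       depth_bin_m: float = 0.5,
                       temp_bin_c: float = 0.1) -> DepthTempSummary:
    """Max/min/mean/modal depth and temperature of one archival series."""
    if not series:
        raise ValueError("depth-temperature series is empty")
    tags = {r.tag_id for r in series}
    if len(tags) > 1:
        raise ValueError("series mixes multiple tags")
    depth = np.array([r.depth_m for r in series])
    temp = np.array([r.temp_c for r in series])
    return DepthTempSummary(
        tag_id=tags.pop(),
        max_depth_m=float(depth.max()),
        modal_depth_m=_modal_bin_centre(depth, depth_bin_m),
        mean_depth_m=float(depth.mean()),
        max_temp_c=float(temp.max()),
        min_temp_c=float(temp.min()),
        modal_temp_c=_modal_bin_centre(temp, temp_bin_c),
        mean_temp_c=float(temp.mean()),
        depth_bin_m=depth_bin_m,
        temp_bin_c=temp_bin_c)
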