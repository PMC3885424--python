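"""Station-level movement summaries: visits, transitions, and linear distances.

A *visit* merges consecutive detections of the same tag at the same receiver
whose inter-detection gaps do not exceed a configurable threshold (default
30 min); a single-detection visit is assigned a floor duration of 1 min.
Directed transitions are counted between successive visits at different
receivers, and per-receiver detection proportions together with the maximum
linear (great-circle) distance between detection sites summarise each
shark's spatial footprint.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km
from .types import Detection, Receiver

SINGLE_DETECTION_FLOOR_MIN = 1.0


@dataclass(frozen=True)
class Visit:
    tag_id: str
    receiver_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_detections: int
    duration_min: float


@dataclass
class TransitionSummary:
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)
    max_linear_distance_km: float = 0.0


def build_visits(detections: Sequence[Detection],
                 gap_threshold_min: float = 30.0) -> list[Visit]:
    """Merge runs of same-receiver detections into visits (per tag)."""
    visits: list[Visit] = []
    by_tag: dict[str, list[Detection]] = {}
    for d in sorted(detections, key=lambda d: (d.tag_id, d.timestamp)):
        by_tag.setdefault(d.tag_id, []).append(d)
    gap = pd.Timedelta(minutes=gap_threshold_min)
    for tag_id, dets in by_tag.items():
        run: list[Detection] = []
        for d in dets:
            if run and (d.receiver_id != run[-1].receiver_id
                        or d.timestamp - run[-1].timestamp > gap):
                visits.append(_close_visit(run))
                run = []
            run.append(d)
        if run:
            visits.append(_close_visit(run))
    visits.sort(key=lambda v: (v.tag_id, v.start))
    return visits


def _close_visit(run: list[Detection]) -> Visit:
    dur = (run[-1].timestamp - run[0].timestamp).total_seconds() / 60.0
    return Visit(run[0].tag_id, run[0].receiver_id, run[0].timestamp,
                 run[-1].timestamp, len(run),
                 max(dur, SINGLE_DETECTION_FLOOR_MIN))


def transitions(visits: Sequence[Visit],
                receivers: Optional[Sequence[Receiver]] = None) -> TransitionSummary:
    """Directed receiver-to-receiver transition counts and detection shares."""
    summary = TransitionSummary()
    counts: dict[str, int] = {}
    for tag_id in sorted({v.tag_id for v in visits}):
        seq = [v for v in visits if v.tag_id == tag_id]
        for a, b in zip(seq, seq[1:]):
            if a.receiver_id != b.receiver_id:
                key = (a.receiver_id, b.receiver_id)
                summary.edges[key] = summary.edges.get(key, 0) + 1
        for v in seq:
            counts[v.receiver_id] = counts.get(v.receiver_id, 0) + v.n_detections
    total = sum(counts.values())
    if total:
        summary.proportions = {r: c / total for r, c in counts.items()}
    if receivers is not None and counts:
        by_id = {r.receiver_id: r for r in receivers}
        pts = [(by_id[r].lon, by_id[r].lat) for r in counts if r in by_id]
        summary.max_linear_distance_km = _max_pairwise_km(pts)
    return summary


def _max_pairwise_km(points: list[tuple[float, float]]) -> float:
    if len(points) < 2:
        return 0.0
    lon = np.array([p[0] for p in points])
    lat = np.array([p[1] for p in points])
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    return float(np.max(d))


def max_linear_distance(detections: Sequence[Detection],
                        receivers: Sequence[Receiver],
                        release_point: Optional[tuple[float, float]] = None) -> float:
    """Max pairwise great-circle distance over the detection-site set.

    The set comprises every receiver with at least one detection plus, when
    given, the release point, so a shark detected at a single station far
    from its tagging site still reports that displacement.
    """
    by_id = {r.receiver_id: r for r in receivers}
    sites: dict[str, tuple[float, float]] = {}
    for d in detections:
        if d.receiver_id not in by_id:
            raise KeyError(f"unknown receiver id {d.receiver_id!r}")
        r = by_id[d.receiver_id]
        sites[d.receiver_id] = (r.lon, r.lat)
    pts = list(sites.values())
    if release_point is not None:
        pts.append((float(release_point[0]), float(release_point[1])))
    return _max_pairwise_km(pts)
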