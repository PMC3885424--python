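"""Location-class and swim-speed plausibility filter for Argos fixes.

High-accuracy fixes (classes 3, 2 and 1) are always kept and become anchors
for later fixes.  Class Z fixes carry no coordinates and are dropped.  Coarse
fixes (classes 0, A and B) are kept only if they lie within a realistic
swimming distance — ``vmax`` (default 3.5 km/h) times the elapsed time — of
the most recent prior anchor, where anchors are previously kept class 1-3
fixes, the capture location, and acoustic receiver detections.  Kept coarse
fixes are deliberately *not* promoted to anchors, so a low-accuracy fix can
never vouch for a later one.  Elapsed time is floored at one minute to avoid
division artefacts for near-simultaneous fixes.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geo import haversine_km
from .types import ArgosPosition

KEEP_CLASSES = ("3", "2", "1")
ELAPSED_FLOOR_H = 1.0 / 60.0


@dataclass(frozen=True)
class Anchor:
    time: pd.Timestamp
    lon: float
    lat: float


@dataclass(frozen=True)
class FilterDecision:
    position: ArgosPosition
    kept: bool
    reason: str  # class_1_3 | within_speed_of_anchor | rejected_speed
    #            | rejected_class_z | no_anchor


def filter_positions(positions: Sequence[ArgosPosition],
                     anchors: Sequence[tuple[pd.Timestamp, float, float]],
                     vmax_kmh: float = 3.5) -> list[FilterDecision]:
    """Apply the class/speed plausibility rule to a time-sorted fix sequence."""
    if not anchors:
        raise ValueError("anchor set must contain at least the capture location")
    times = [p.timestamp for p in positions]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("positions must be sorted by time")

    pool = sorted((Anchor(pd.Timestamp(t), float(lon), float(lat))
                   for t, lon, lat in anchors), key=lambda a: a.time)
    pool_times = [a.time for a in pool]

    decisions: list[FilterDecision] = []
    for p in positions:
        if p.loc_class == "Z":
            decisions.append(FilterDecision(p, False, "rejected_class_z"))
            continue
        if p.loc_class in KEEP_CLASSES:
            decisions.append(FilterDecision(p, True, "class_1_3"))
            i = bisect.bisect_right(pool_times, p.timestamp)
            pool.insert(i, Anchor(p.timestamp, p.lon, p.lat))
            pool_times.insert(i, p.timestamp)
            continue
        # class 0/A/B: check against the most recent anchor at or before the fix
        i = bisect.bisect_right(pool_times, p.timestamp)
        if i == 0:
            decisions.append(FilterDecision(p, False, "no_anchor"))
            continue
        a = pool[i - 1]
        dist = haversine_km(a.lon, a.lat, p.lon, p.lat)
        hours = max((p.timestamp - a.time).total_seconds() / 3600.0,
                    ELAPSED_FLOOR_H)
        if dist <= vmax_kmh * hours:
            decisions.append(FilterDecision(p, True, "within_speed_of_anchor"))
        else:
            decisions.append(FilterDecision(p, False, "rejected_speed"))
    return decisions


def kept_positions(decisions: Sequence[FilterDecision]) -> list[ArgosPosition]:
    return [d.position for d in decisions if d.kept]
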