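"""Monitoring windows, the Residency Index, and behaviour classification.

The Residency Index (RI) of a shark is the number of distinct calendar days
on which it was detected by an acoustic array, divided by the number of days
it could possibly have been detected (its transmitter's estimated battery
life, capped by the last service date of the array).  On top of detection-day
bookkeeping, each shark is assigned exactly one of four occurrence
categories, evaluated in precedence order:

1. **Resident** — detected in ten or more distinct calendar months within
   every year-block of its monitoring window, and RI > 0.30;
2. **Pseudo-resident** — five or more detected days in each of three or more
   calendar months within a single year-block, and RI < 0.30;
3. **Transient** — re-detected after a gap of more than 31 days since the
   previous detection (or since release);
4. **Passer-by** — never detected after the first 31 days post-release
   (including sharks never detected at all), and the fallback for any
   pattern the first three rules do not capture.

Year-blocks are consecutive 365-day intervals starting at release; a final
partial block is held to the ten-month requirement only if it spans at least
ten calendar months.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Detection, Receiver, TagDeployment

BEHAVIOURS = ("passer_by", "transient", "pseudo_resident", "resident")


def _naive(ts: pd.Timestamp) -> pd.Timestamp:
    """UTC wall-clock copy without tz info (calendar arithmetic only)."""
    return ts.tz_localize(None) if ts.tzinfo is not None else ts


@dataclass(frozen=True)
class MonitoringWindow:
    """Interval during which a tag could plausibly be detected."""

    tag_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    potential_days: int

    def __post_init__(self):
        if self.end <= self.start and self.potential_days != 1:
            raise ValueError("monitoring window must be non-empty")
        if self.potential_days < 1:
            raise ValueError("potential_days must be >= 1")


@dataclass
class DailyDetectionTable:
    """Per (tag, array, calendar day) detection flags and counts."""

    table: pd.DataFrame  # columns: tag_id, array_name, date, n_detections

    @classmethod
    def from_detections(cls, detections: Sequence[Detection],
                        receivers: Sequence[Receiver]) -> "DailyDetectionTable":
        arrays = {r.receiver_id: r.array_name for r in receivers}
        rows = [(d.tag_id, arrays.get(d.receiver_id, "unknown"),
                 d.timestamp.tz_convert("UTC").normalize()) for d in detections]
        if not rows:
            df = pd.DataFrame(columns=["tag_id", "array_name", "date", "n_detections"])
        else:
            df = (pd.DataFrame(rows, columns=["tag_id", "array_name", "date"])
                  .groupby(["tag_id", "array_name", "date"], as_index=False)
                  .size().rename(columns={"size": "n_detections"}))
        return cls(df.sort_values(["tag_id", "array_name", "date"])
                   .reset_index(drop=True))

    def detected_days(self, tag_id: str) -> list[pd.Timestamp]:
        sub = self.table[self.table.tag_id == tag_id]
        return sorted(sub.date.unique())

    def monthly_detected_days(self, tag_id: str) -> pd.Series:
        """Count of detected days per calendar month (PeriodIndex)."""
        days = [_naive(pd.Timestamp(d)) for d in self.detected_days(tag_id)]
        if not days:
            return pd.Series(dtype=int)
        periods = pd.PeriodIndex([d.to_period("M") for d in days])
        return pd.Series(1, index=periods).groupby(level=0).sum()


@dataclass
class ResidencySummary:
    tag_id: str
    array_name: str
    days_monitored: int        # release to last detection, calendar days
    days_detected: int
    n_detections: int
    mean_gap_days: Optional[float]
    residency_index: float
    behaviour: str


def monitoring_window(tag: TagDeployment,
                      receivers: Sequence[Receiver]) -> MonitoringWindow:
    """Battery life capped by the last array service time, in calendar days.

    The release day counts as day 0; ``potential_days`` is the day index of
    the window's final day, floored at 1 (a same-day window is one day).
    """
    if not receivers:
        raise ValueError("no receivers supplied")
    last_service = max(r.deployed_to for r in receivers)
    if tag.release_time >= last_service:
        raise ValueError(f"no overlap: tag {tag.tag_id} released after all "
                         "array retrievals")
    battery_end = tag.release_time + pd.Timedelta(days=tag.battery_days)
    end = min(battery_end, last_service)
    n = (end.normalize() - tag.release_time.normalize()).days
    return MonitoringWindow(tag.tag_id, tag.release_time, end, max(n, 1))


def residency_index(daily: DailyDetectionTable, window: MonitoringWindow,
                    tag_id: Optional[str] = None) -> float:
    """Distinct detected days / potential monitoring days, in [0, 1]."""
    tag_id = tag_id or window.tag_id
    n_days = len(daily.detected_days(tag_id))
    return min(n_days / window.potential_days, 1.0)


def _year_blocks(window: MonitoringWindow) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    blocks = []
    start = window.start.normalize()
    end = window.end.normalize()
    while start <= end:
        blocks.append((start, min(start + pd.Timedelta(days=364), end)))
        start = start + pd.Timedelta(days=365)
    return blocks


def _months_spanned(a: pd.Timestamp, b: pd.Timestamp) -> int:
    return (b.year - a.year) * 12 + (b.month - a.month) + 1


def classify_behaviour(daily: DailyDetectionTable, window: MonitoringWindow,
                       ri: Optional[float] = None,
                       ri_threshold: float = 0.30,
                       gap_days: int = 31,
                       tag_id: Optional[str] = None) -> str:
    """Assign one of the four occurrence categories (see module docstring)."""
    tag_id = tag_id or window.tag_id
    if ri is None:
        ri = residency_index(daily, window, tag_id)
    days = [pd.Timestamp(d) for d in daily.detected_days(tag_id)]
    release_day = window.start.normalize()

    # Resident: >=10 distinct detected months in every (sufficiently long)
    # year-block, and RI strictly above the threshold.
    if days and ri > ri_threshold:
        ok = True
        for lo, hi in _year_blocks(window):
            if _months_spanned(lo, hi) < 10:
                continue  # short final block cannot be held to 10 months
            months = {(d.year, d.month) for d in days if lo <= d <= hi}
            if len(months) < 10:
                ok = False
                break
        if ok:
            return "resident"

    # Pseudo-resident: >=3 calendar months with >=5 detected days within a
    # single year-block, and RI strictly below the threshold.
    if days and ri < ri_threshold:
        for lo, hi in _year_blocks(window):
            in_block = [d for d in days if lo <= d <= hi]
            counts = pd.Series(1, index=pd.PeriodIndex(
                [_naive(d).to_period("M") for d in in_block])) if in_block \
                else pd.Series(dtype=int)
            per_month = counts.groupby(level=0).sum() if not counts.empty else counts
            if (per_month >= 5).sum() >= 3:
                return "pseudo_resident"

    # Transient: any re-detection after a gap > gap_days from the previous
    # detection day (or from release).
    if days:
        anchors = [release_day] + days
        gaps = np.diff([a.value for a in anchors]) / 86_400_000_000_000
        if np.any(gaps > gap_days):
            return "transient"

    # Passer-by: nothing after day `gap_days` post-release — and the fallback
    # for degenerate patterns outside the study's categories.
    return "passer_by"


def detection_day_summary(detections: Sequence[Detection],
                          window: MonitoringWindow,
                          receivers: Sequence[Receiver],
                          ri_threshold: float = 0.30,
                          gap_days: int = 31) -> ResidencySummary:
    """Fill the per-shark summary row (detection days, gaps, RI, behaviour)."""
    tag_id = window.tag_id
    mine = sorted((d for d in detections if d.tag_id == tag_id),
                  key=lambda d: d.timestamp)
    daily = DailyDetectionTable.from_detections(mine, receivers)
    days = [pd.Timestamp(d) for d in daily.detected_days(tag_id)]
    if mine:
        monitored = (mine[-1].timestamp.normalize()
                     - window.start.normalize()).days
        monitored = max(monitored, 1)
    else:
        monitored = 0
    if len(days) > 1:
        gaps = np.diff([d.value for d in days]) / 86_400_000_000_000
        mean_gap = float(np.mean(gaps))
    else:
        mean_gap = None
    ri = residency_index(daily, window, tag_id)
    behaviour = classify_behaviour(daily, window, ri, ri_threshold=ri_threshold,
                                   gap_days=gap_days, tag_id=tag_id)
    arrays = sorted({r.array_name for r in receivers
                     if r.receiver_id in {d.receiver_id for d in mine}})
    return ResidencySummary(tag_id=tag_id,
                            array_name=";".join(arrays) if arrays else "",
                            days_monitored=monitored,
                            days_detected=len(days),
                            n_detections=len(mine),
                            mean_gap_days=mean_gap,
                            residency_index=ri,
                            behaviour=behaviour)


def summary_table(detections: Sequence[Detection], tags: Sequence[TagDeployment],
                  receivers: Sequence[Receiver],
                  ri_threshold: float = 0.30, gap_days: int = 31) -> pd.DataFrame:
    """One summary row per tagged shark, mirroring the acoustic summary table."""
    rows = []
    for tag in tags:
        window = monitoring_window(tag, receivers)
        s = detection_day_summary(detections, window, receivers,
                                  ri_threshold=ri_threshold, gap_days=gap_days)
        rows.append({"tag_id": s.tag_id, "array_name": s.array_name,
                     "potential_days": window.potential_days,
                     "days_monitored": s.days_monitored,
                     "days_detected": s.days_detected,
                     "n_detections": s.n_detections,
                     "mean_gap_days": (np.nan if s.mean_gap_days is None
                                       else s.mean_gap_days),
                     "residency_index": s.residency_index,
                     "behaviour": s.behaviour})
    return pd.DataFrame(rows)
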