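"""Day/night detection split and the equal-expectation chi-square test.

Detections are assigned to fixed diel windows on the dataset's local wall
clock (a fixed UTC offset, no daylight saving): day is [06:00, 18:00) and
night is [18:00, 06:00).  Diel bias per shark is tested with the two-cell
Pearson goodness-of-fit against equal day/night expectation, which for
counts (d, n) reduces to the closed form

    X^2 = (d - n)^2 / (d + n),   p = P(chi^2_1 >= X^2).

No continuity correction is applied.  p-values are printed to three
decimals, with values below 0.001 reported as "<0.001".
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2

from .io import to_local
from .types import Detection

DAY_START_HOUR = 6
NIGHT_START_HOUR = 18


@dataclass(frozen=True)
class DielCounts:
    tag_id: str
    day_count: int    # 06:00-17:59 local
    night_count: int  # 18:00-05:59 local

    def __post_init__(self):
        if self.day_count < 0 or self.night_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.day_count + self.night_count


def is_day(local_hour: int) -> bool:
    return DAY_START_HOUR <= local_hour < NIGHT_START_HOUR


def diel_split(detections: Sequence[Detection], utc_offset_hours: float,
               tag_id: str | None = None) -> DielCounts:
    """Count day and night detections for one tag on the local clock."""
    if tag_id is None:
        tags = {d.tag_id for d in detections}
        if len(tags) > 1:
            raise ValueError("multiple tags present; pass tag_id explicitly")
        tag_id = tags.pop() if tags else ""
    day = night = 0
    for d in detections:
        if d.tag_id != tag_id:
            continue
        if is_day(to_local(d.timestamp, utc_offset_hours).hour):
            day += 1
        else:
            night += 1
    return DielCounts(tag_id, day, night)


def diel_chi_square(counts: DielCounts) -> tuple[float, float]:
    """Equal-expectation 1-df chi-square statistic and upper-tail p-value."""
    total = counts.total
    if total < 1:
        raise ValueError("chi-square requires at least one detection")
    stat = (counts.day_count - counts.night_count) ** 2 / total
    p = float(chi2.sf(stat, df=1))
    return float(stat), p


def format_p(p: float) -> str:
    """Journal-style p formatting: three decimals, '<0.001' below 0.001."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"
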