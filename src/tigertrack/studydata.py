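"""Worked-example inputs from the Coral Sea tiger-shark telemetry study.

These are the small printed summary tables of the original study this
package re-implements: per-shark day/night detection counts with their
published p-values, satellite-tag deployment durations, and the acoustic
worked examples (monitoring windows and detected-day patterns) used
throughout the tests and the acceptance checks.  They are *inputs* — the
pipeline recomputes every derived quantity from them.
"""
from __future__ import annotations

#: (tag, day_count, night_count, printed_p) — diel detection summaries.
#: The study's printed chi-square statistic column is internally inconsistent
#: with these p-values and is not carried; the p-value column is what the
#: equal-expectation test reproduces.
DIEL_COUNTS = [
    ("TS1", 30, 9, "<0.001"),
    ("TS2", 5, 50, "<0.001"),
    ("TS4", 20, 15, "0.398"),
    ("TS9", 56, 35, "0.028"),
    ("TS10", 44, 58, "0.166"),
    ("TS16", 474, 389, "0.004"),
    ("TS17", 62, 374, "<0.001"),
    ("TS18", 1081, 1868, "<0.001"),
    ("TS19", 526, 522, "0.902"),
]

#: PSAT deployment durations (days) for the nine pop-up tags that reported.
PSAT_DURATIONS_DAYS = {"TS6": 4, "TS8": 19, "TS9": 181, "TS11": 210,
                       "TS16": 15, "TS17": 4, "TS18": 93, "TS25": 7,
                       "TS29": 78}

#: Fin-mounted (SPOT) tag transmission durations (days).
SPOT_DURATIONS_DAYS = {"TS3": 38, "TS13": 13, "TS14": 7}

#: Acoustic worked examples: detected-day patterns over monitoring windows.
#: TS16: 155 detected days of a 432-day window (residency index 155/432).
#: TS19: 183 detected days spread over >=10 months of a 432-day window.
#: TS24: detection at release then a single re-detection at day 326.
ACOUSTIC_EXAMPLES = {
    "TS16": {"days_detected": 155, "potential_days": 432},
    "TS19": {"days_detected": 183, "potential_days": 432},
    "TS24": {"detected_day_offsets": [0, 326], "potential_days": 432},
}

#: Deepest recorded dive (m) of the study, used as a scenario parameter.
MAX_RECORDED_DIVE_M = 1136.0
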