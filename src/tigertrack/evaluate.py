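"""Parameter-recovery harnesses over the synthetic generator.

These routines answer "does the analysis recover what the simulator did?":
behaviour classification against the simulated movement regime, and
detection-day bookkeeping against the truth sidecar.  They are the package's
own end-to-end verification surface and are reused by the acceptance script.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residency import detection_day_summary, monitoring_window
from .synthetic import (REGIMES, SimulationConfig, make_receivers, make_tag,
                        simulate_detections, simulate_track)


@dataclass
class RecoveryResult:
    regime: str
    n_seeds: int
    n_correct: int
    labels: list[str]

    @property
    def rate(self) -> float:
        return self.n_correct / self.n_seeds


def classify_simulated(config: SimulationConfig) -> str:
    """Simulate one shark end to end and return its behaviour label."""
    truth = simulate_track(config)
    receivers = make_receivers(config)
    detections = simulate_detections(truth, receivers, config)
    tag = make_tag(config)
    window = monitoring_window(tag, receivers)
    return detection_day_summary(detections, window, receivers).behaviour


def regime_recovery(n_seeds: int = 20, duration_days: int = 400,
                    base_seed: int = 0,
                    regimes: tuple[str, ...] = REGIMES
                    ) -> dict[str, RecoveryResult]:
    """Fraction of simulated sharks whose regime the classifier recovers."""
    out = {}
    for ri, regime in enumerate(regimes):
        labels = []
        for s in range(n_seeds):
            seed = int((base_seed + 1000 * ri + s) % (2 ** 31 - 1))
            cfg = SimulationConfig(seed=seed, duration_days=duration_days,
                                   regime=regime)
            labels.append(classify_simulated(cfg))
        n_ok = sum(1 for lab in labels if lab == regime)
        out[regime] = RecoveryResult(regime, n_seeds, n_ok, labels)
    return out


def days_detected_matches_truth(config: SimulationConfig) -> bool:
    """Residency day counting agrees with the truth sidecar exactly."""
    truth = simulate_track(config)
    receivers = make_receivers(config)
    detections = simulate_detections(truth, receivers, config)
    tag = make_tag(config)
    window = monitoring_window(tag, receivers)
    summary = detection_day_summary(detections, window, receivers)
    hit = truth.emission_receiver >= 0
    import pandas as pd
    days = {(truth.t0 + pd.Timedelta(seconds=float(s))).normalize()
            for s in truth.emission_times[hit]}
    return summary.days_detected == len(days)
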