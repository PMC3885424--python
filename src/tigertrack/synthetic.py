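"""Synthetic tiger-shark telemetry with known ground truth.

Generates every input the pipeline consumes — acoustic detections on a
receiver array, Argos surface fixes with class-dependent error, archival
depth-temperature series and a bathymetry grid — from a single seeded
movement simulation, so that downstream residency metrics, behaviour
classification, filtering and kernel volumes can be checked against truth.

The movement model is a first-order correlated random walk on a local
tangent plane (km), with Ornstein-Uhlenbeck-style attraction towards a
target that switches between the receiver-array centroid and distant
off-array waypoints according to a per-regime bout schedule.  The four
schedules reproduce the four occurrence patterns used to classify sharks:

- ``resident``: permanently attracted to the array centroid;
- ``pseudo_resident``: short on-array bouts (~8 d) alternating with
  longer off-array excursions (~30 d), so detected repeatedly but on a
  minority of days;
- ``transient``: an initial few days on-array, then long absences
  (~2 months) punctuated by brief revisits;
- ``passer_by``: departs the array region permanently within the first
  ten days and keeps receding.

The acoustic observation process emits pings at i.i.d. uniform delays in
the tag's programmed delay window and detects each ping at its nearest
receiver with probability that decays logistically with distance and is
exactly zero beyond the maximum detection range.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as tio
from .geo import haversine_km, project_xy, unproject_xy
from .types import (ArgosPosition, BathymetryGrid, Detection, DepthTempRecord,
                    Receiver, TagDeployment)

REGIMES = ("resident", "pseudo_resident", "transient", "passer_by")

#: default simulation origin: Chesterfield-reef-like mid-Coral-Sea location
DEFAULT_ORIGIN = (158.3, -19.9)
DEFAULT_T0 = pd.Timestamp("2010-08-12T00:00:00Z")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class RegimeParams:
    """Movement-kernel parameters of the correlated random walk."""

    attraction: float = 0.06      # OU mean-reversion per step towards the target
    step_km: float = 0.6          # innovation scale per step (km)
    persistence: float = 0.5      # AR(1) coefficient of the step vector, in [0, 1)

    def __post_init__(self):
        if not (0.0 <= self.attraction <= 1.0):
            raise ConfigError("attraction must be in [0, 1]")
        if self.step_km < 0:
            raise ConfigError("step_km must be >= 0")
        if not (0.0 <= self.persistence < 1.0):
            raise ConfigError("persistence must be in [0, 1)")


@dataclass(frozen=True)
class DiveParams:
    """Two-state dive behaviour: shallow occupancy plus episodic deep dives."""

    shallow_mean_m: float = 15.0
    shallow_sd_m: float = 10.0
    shallow_max_m: float = 40.0
    deep_rate_per_day: float = 2.0
    deep_depth_min_m: float = 100.0
    deep_depth_max_m: float = 1136.0
    max_depth_m: float = 1200.0
    dive_duration_min: float = 45.0
    surface_temp_c: float = 27.0
    deep_temp_c: float = 4.5
    temp_scale_m: float = 350.0   # e-folding depth of the temperature profile
    temp_noise_sd_c: float = 0.3
    sample_minutes: float = 10.0

    def __post_init__(self):
        if self.shallow_max_m <= 0 or self.max_depth_m <= 0:
            raise ConfigError("depth bounds must be positive")
        if self.deep_rate_per_day < 0:
            raise ConfigError("deep-dive rate must be >= 0")
        if not (0 < self.deep_depth_min_m <= self.deep_depth_max_m <= self.max_depth_m):
            raise ConfigError("deep-dive depth range invalid")

    def temp_at_depth(self, depth_m):
        """Monotone-decreasing mean temperature profile (deg C)."""
        depth_m = np.asarray(depth_m, dtype=float)
        return (self.deep_temp_c
                + (self.surface_temp_c - self.deep_temp_c)
                * np.exp(-depth_m / self.temp_scale_m))


#: Argos positional error scale (m) by location class; classes 0/A/B share the
#: coarse ~3 km scale and Z fixes carry no usable coordinates at all.
DEFAULT_ARGOS_ERROR_M = {"3": 250.0, "2": 500.0, "1": 1500.0,
                         "0": 3000.0, "A": 3000.0, "B": 3000.0}
DEFAULT_ARGOS_CLASS_MIX = {"3": 0.10, "2": 0.15, "1": 0.20,
                           "0": 0.15, "A": 0.20, "B": 0.15, "Z": 0.05}


def default_receiver_layout(n: int = 7, extent_km: float = 22.0,
                            origin=DEFAULT_ORIGIN) -> list[tuple[float, float]]:
    """n receivers along a lagoon transect spanning ``extent_km`` end to end."""
    x = np.linspace(-extent_km / 2.0, extent_km / 2.0, n)
    y = np.where(np.arange(n) % 2 == 0, 0.8, -0.8)  # slight stagger off the line
    lon, lat = unproject_xy(x, y, *origin)
    return list(zip(lon.tolist(), lat.tolist()))


@dataclass
class SimulationConfig:
    seed: int = 0
    duration_days: int = 400
    step_minutes: float = 15.0
    regime: str = "resident"
    regime_params: RegimeParams = field(default_factory=RegimeParams)
    receiver_layout: list[tuple[float, float]] = field(
        default_factory=default_receiver_layout)
    detection_range_m: tuple[float, float] = (400.0, 800.0)
    detection_p_at_half_range: float = 0.5
    tag_delay_s: tuple[float, float] = (40.0, 80.0)
    battery_days: int = 835
    argos_error_m: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_ERROR_M))
    argos_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_CLASS_MIX))
    argos_per_day: float = 1.0
    dive_params: DiveParams = field(default_factory=DiveParams)
    origin: tuple[float, float] = DEFAULT_ORIGIN
    t0: pd.Timestamp = DEFAULT_T0

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ConfigError("duration_days must be positive")
        if self.step_minutes <= 0:
            raise ConfigError("step_minutes must be positive")
        if self.regime not in REGIMES:
            raise ConfigError(f"regime must be one of {REGIMES}")
        rmin, rmax = self.detection_range_m
        if not (0 < rmin <= rmax):
            raise ConfigError("detection range must satisfy 0 < min <= max")
        if not (0.0 < self.detection_p_at_half_range < 1.0):
            raise ConfigError("detection_p_at_half_range must be in (0, 1)")
        dmin, dmax = self.tag_delay_s
        if not (0 < dmin < dmax):
            raise ConfigError("tag delay must satisfy 0 < min < max")
        if not self.receiver_layout:
            raise ConfigError("receiver_layout must be non-empty")
        if any(v <= 0 for v in self.argos_error_m.values()):
            raise ConfigError("Argos error scales must be positive")
        if self.argos_per_day <= 0:
            raise ConfigError("argos_per_day must be positive")


@dataclass
class TruthRecord:
    """Ground truth of one simulated shark: positions, pings and outcomes."""

    config: SimulationConfig
    regime: str
    step_times: np.ndarray          # seconds since t0, per movement step
    x_km: np.ndarray
    y_km: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth_m: np.ndarray
    on_array: np.ndarray            # bool per step: attracted to array centroid
    emission_times: np.ndarray      # seconds since t0, per acoustic ping
    emission_x_km: np.ndarray
    emission_y_km: np.ndarray
    emission_receiver: Optional[np.ndarray] = None  # index into receivers, -1 = missed
    argos_truth: Optional[pd.DataFrame] = None      # per-fix truth incl. outlier flag

    @property
    def t0(self) -> pd.Timestamp:
        return self.config.t0


def _bout_schedule(regime: str, n_steps: int, dt_days: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean per-step mask: True while the shark is in its on-array mode."""
    on = np.zeros(n_steps, dtype=bool)
    t = 0
    if regime == "resident":
        on[:] = True
    elif regime == "pseudo_resident":
        state = True
        while t < n_steps:
            dur_days = rng.uniform(6.0, 10.0) if state else rng.uniform(26.0, 34.0)
            n = max(1, int(round(dur_days / dt_days)))
            on[t:t + n] = state
            t += n
            state = not state
    elif regime == "transient":
        state = True
        first = True
        while t < n_steps:
            if state:
                dur_days = rng.uniform(2.0, 4.0) if not first else rng.uniform(2.0, 4.0)
                first = False
            else:
                dur_days = rng.uniform(50.0, 80.0)
            n = max(1, int(round(dur_days / dt_days)))
            on[t:t + n] = state
            t += n
            state = not state
    elif regime == "passer_by":
        n = max(1, int(round(rng.uniform(4.0, 8.0) / dt_days)))
        on[:n] = True
    return on


def simulate_track(config: SimulationConfig) -> TruthRecord:
    """Simulate the true movement path and acoustic ping times of one shark."""
    rng = np.random.default_rng(config.seed)
    dt_days = config.step_minutes / 1440.0
    n_steps = int(round(config.duration_days / dt_days)) + 1
    p = config.regime_params
    on = _bout_schedule(config.regime, n_steps, dt_days, rng)

    # waypoints for off-array excursions, drawn once per simulation
    away_bearing = rng.uniform(0.0, 2.0 * np.pi)
    away_dist = 80.0 if config.regime != "passer_by" else 400.0
    away_target = np.array([np.cos(away_bearing), np.sin(away_bearing)]) * away_dist

    x = np.empty(n_steps)
    y = np.empty(n_steps)
    x[0] = y[0] = 0.0  # release at the array centroid
    pos = np.zeros(2)
    step = np.zeros(2)
    innov = (rng.standard_normal((n_steps, 2))
             * p.step_km * np.sqrt(max(1.0 - p.persistence ** 2, 0.0)))
    centroid = np.zeros(2)
    depart_idx = int(np.argmax(~on)) if (~on).any() else n_steps
    # passer-by guarantee: once departed the radial distance from the array
    # never drops below an outward-moving floor, so no late re-entry is possible
    drift_km_day = 12.0
    for i in range(1, n_steps):
        target = centroid if on[i] else away_target
        step = p.persistence * step + innov[i]
        pos = pos + step + p.attraction * (target - pos)
        if config.regime == "passer_by" and i >= depart_idx:
            floor = drift_km_day * (i - depart_idx) * dt_days
            r = float(np.hypot(pos[0], pos[1]))
            if r < floor:
                direction = (away_target / away_dist if r < 1e-9
                             else pos / r)
                pos = direction * floor
        x[i] = pos[0]
        y[i] = pos[1]

    # per-step depth: shallow occupancy with occasional deep excursions
    dp = config.dive_params
    depth = np.abs(rng.normal(dp.shallow_mean_m, dp.shallow_sd_m, n_steps))
    depth = np.clip(depth, 0.0, dp.shallow_max_m)
    n_dives = rng.poisson(dp.deep_rate_per_day * config.duration_days)
    if n_dives > 0:
        dive_at = rng.integers(0, n_steps, n_dives)
        depth[dive_at] = np.clip(
            rng.uniform(dp.deep_depth_min_m, dp.deep_depth_max_m, n_dives),
            0.0, dp.max_depth_m)

    step_times = np.arange(n_steps) * config.step_minutes * 60.0
    lon, lat = unproject_xy(x, y, *config.origin)

    # acoustic ping times: i.i.d. uniform delays in the programmed window
    total_s = config.duration_days * 86400.0
    dmin, dmax = config.tag_delay_s
    n_emis = int(total_s / dmin) + 2
    delays = rng.uniform(dmin, dmax, n_emis)
    etimes = np.cumsum(delays)
    etimes = etimes[etimes <= total_s]
    ex = np.interp(etimes, step_times, x)
    ey = np.interp(etimes, step_times, y)

    return TruthRecord(config=config, regime=config.regime, step_times=step_times,
                       x_km=x, y_km=y, lon=lon, lat=lat, depth_m=depth,
                       on_array=on, emission_times=etimes,
                       emission_x_km=ex, emission_y_km=ey)


def detection_probability(distance_m, config: SimulationConfig):
    """Probability a ping at ``distance_m`` from a receiver is detected.

    Logistic decay with p = detection_p_at_half_range at half the maximum
    range, truncated to exactly zero beyond the maximum range.
    """
    rmin, rmax = config.detection_range_m
    d = np.asarray(distance_m, dtype=float)
    half = rmax / 2.0
    slope = rmax / 8.0
    p = 2.0 * config.detection_p_at_half_range * expit((half - d) / slope)
    p = np.minimum(p, 1.0)
    p = np.where(d > rmax, 0.0, p)
    if np.ndim(distance_m) == 0:
        return float(p)
    return p


def make_receivers(config: SimulationConfig,
                   array_name: str = "sim_array") -> list[Receiver]:
    """Receiver objects for the configured layout, deployed over the full run."""
    t0 = config.t0
    t1 = t0 + pd.Timedelta(days=config.duration_days)
    return [Receiver(f"R{i + 1:02d}", array_name, lon, lat, 15.0, t0, t1)
            for i, (lon, lat) in enumerate(config.receiver_layout)]


def make_tag(config: SimulationConfig, tag_id: str = "T001",
             shark_id: Optional[str] = None) -> TagDeployment:
    """A tag deployment consistent with the simulation configuration."""
    from .types import TAG_CONFIGS
    delay = TAG_CONFIGS[config.battery_days]
    lon0, lat0 = config.origin
    return TagDeployment(tag_id=tag_id, shark_id=shark_id or f"shark_{tag_id}",
                         sex="F", total_length_cm=300.0, maturity="sub_adult",
                         clasper_state="not_applicable", release_time=config.t0,
                         release_lon=lon0, release_lat=lat0,
                         battery_days=config.battery_days, delay_s=delay)


def simulate_detections(truth: TruthRecord, receivers: Sequence[Receiver],
                        config: SimulationConfig,
                        tag_id: str = "T001") -> list[Detection]:
    """Run the detection process over the truth's ping times.

    Each ping can be logged by at most its nearest receiver, with probability
    :func:`detection_probability` of the ping-receiver distance.  Fills
    ``truth.emission_receiver`` as a side effect (-1 = missed).
    """
    if not receivers:
        raise ConfigError("receivers must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rx, ry = project_xy(np.array([r.lon for r in receivers]),
                        np.array([r.lat for r in receivers]), *config.origin)
    dx = truth.emission_x_km[:, None] - rx[None, :]
    dy = truth.emission_y_km[:, None] - ry[None, :]
    dist_m = np.hypot(dx, dy) * 1000.0
    nearest = np.argmin(dist_m, axis=1)
    d_near = dist_m[np.arange(dist_m.shape[0]), nearest]
    pdet = detection_probability(d_near, config)
    hit = rng.uniform(size=pdet.shape) < pdet
    outcome = np.where(hit, nearest, -1)
    truth.emission_receiver = outcome
    idx = np.nonzero(hit)[0]
    t0 = truth.t0
    detections = [Detection(tag_id, receivers[nearest[i]].receiver_id,
                            t0 + pd.Timedelta(seconds=float(truth.emission_times[i])))
                  for i in idx]
    detections.sort(key=lambda d: d.timestamp)
    return detections


def simulate_argos(truth: TruthRecord, config: SimulationConfig,
                   tag_id: str = "T001",
                   n_outliers: int = 0,
                   outlier_offset_km: float = 500.0) -> list[ArgosPosition]:
    """Subsample surfacing fixes from the track and add class-dependent error.

    Optionally injects ``n_outliers`` gross class-B outliers displaced by
    ``outlier_offset_km``; the per-fix truth (including the outlier flag) is
    stored in ``truth.argos_truth``.
    """
    if truth.step_times.size == 0:
        raise ConfigError("truth track is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    total_s = float(truth.step_times[-1])
    n_fix = max(1, rng.poisson(config.argos_per_day * total_s / 86400.0))
    times = np.sort(rng.uniform(0.0, total_s, n_fix))
    tx = np.interp(times, truth.step_times, truth.x_km)
    ty = np.interp(times, truth.step_times, truth.y_km)
    classes = list(config.argos_class_mix)
    probs = np.array([config.argos_class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    cls = rng.choice(classes, size=n_fix, p=probs)

    is_outlier = np.zeros(n_fix, dtype=bool)
    if n_outliers > 0:
        eligible = np.nonzero(cls != "Z")[0]
        pick = rng.choice(eligible, size=min(n_outliers, eligible.size),
                          replace=False)
        cls[pick] = "B"
        is_outlier[pick] = True

    positions: list[ArgosPosition] = []
    rows = []
    for i in range(n_fix):
        t = truth.t0 + pd.Timedelta(seconds=float(times[i]))
        c = str(cls[i])
        if c == "Z":
            positions.append(ArgosPosition(tag_id, t, "Z"))
            rows.append((times[i], np.nan, np.nan, c, False))
            continue
        scale_km = config.argos_error_m[c] / 1000.0
        ex, ey = tx[i], ty[i]
        if is_outlier[i]:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            ex += outlier_offset_km * np.cos(theta)
            ey += outlier_offset_km * np.sin(theta)
        ex += rng.normal(0.0, scale_km)
        ey += rng.normal(0.0, scale_km)
        lon, lat = unproject_xy(ex, ey, *config.origin)
        positions.append(ArgosPosition(tag_id, t, c, float(lon), float(lat)))
        rows.append((times[i], tx[i], ty[i], c, bool(is_outlier[i])))
    truth.argos_truth = pd.DataFrame(
        rows, columns=["time_s", "true_x_km", "true_y_km", "loc_class", "is_outlier"])
    return positions


def simulate_depth_series(config: SimulationConfig,
                          tag_id: str = "T001",
                          duration_days: Optional[float] = None
                          ) -> list[DepthTempRecord]:
    """Archival depth-temperature series: shallow occupancy + episodic deep dives."""
    dp = config.dive_params
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    days = float(duration_days if duration_days is not None else config.duration_days)
    dt_s = dp.sample_minutes * 60.0
    n = int(days * 86400.0 / dt_s) + 1
    depth = np.abs(rng.normal(dp.shallow_mean_m, dp.shallow_sd_m, n))
    depth = np.clip(depth, 0.0, dp.shallow_max_m)

    n_dives = rng.poisson(dp.deep_rate_per_day * days)
    half_w = max(1, int(round(dp.dive_duration_min * 60.0 / dt_s / 2.0)))
    for _ in range(n_dives):
        centre = int(rng.integers(0, n))
        peak = float(np.clip(rng.uniform(dp.deep_depth_min_m, dp.deep_depth_max_m),
                             0.0, dp.max_depth_m))
        lo = max(0, centre - half_w)
        hi = min(n, centre + half_w + 1)
        # V-shaped excursion: linear descent to the peak depth and back
        for j in range(lo, hi):
            frac = 1.0 - abs(j - centre) / float(half_w)
            depth[j] = max(depth[j], frac * peak)

    temp = dp.temp_at_depth(depth) + rng.normal(0.0, dp.temp_noise_sd_c, n)
    temp = np.clip(temp, -4.9, 44.9)
    t0 = config.t0
    return [DepthTempRecord(tag_id, t0 + pd.Timedelta(seconds=i * dt_s),
                            float(depth[i]), float(temp[i])) for i in range(n)]


def make_bathymetry(extent: tuple[float, float, float, float], cell_km: float,
                    seafloor_fn: Callable) -> BathymetryGrid:
    """Evaluate ``seafloor_fn(lon, lat)`` (vectorised, metres) on a regular grid.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max) in degrees.
    """
    if cell_km <= 0:
        raise ConfigError("cell size must be positive")
    lon_min, lon_max, lat_min, lat_max = extent
    mid_lat = 0.5 * (lat_min + lat_max)
    dlat = cell_km / 111.19
    dlon = cell_km / (111.19 * max(np.cos(np.radians(mid_lat)), 1e-6))
    lon = np.arange(lon_min, lon_max + dlon / 2.0, dlon)
    lat = np.arange(lat_min, lat_max + dlat / 2.0, dlat)
    lon2, lat2 = np.meshgrid(lon, lat)
    depth = np.asarray(seafloor_fn(lon2, lat2), dtype=float)
    if not np.all(np.isfinite(depth)):
        raise ConfigError("seafloor function produced non-finite depths")
    return BathymetryGrid(lon, lat, depth)


def write_truth(truth: TruthRecord, out_dir) -> None:
    """Truth sidecar files for test harnesses: one row per step and per ping."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": truth.step_times, "x_km": truth.x_km,
                  "y_km": truth.y_km, "lon": truth.lon, "lat": truth.lat,
                  "depth_m": truth.depth_m, "on_array": truth.on_array.astype(int),
                  }).to_csv(out_dir / "truth_steps.csv", index=False)
    emis = pd.DataFrame({"time_s": truth.emission_times,
                         "x_km": truth.emission_x_km,
                         "y_km": truth.emission_y_km})
    if truth.emission_receiver is not None:
        emis["receiver_index"] = truth.emission_receiver
    emis.to_csv(out_dir / "truth_emissions.csv", index=False)


def simulate_dataset(config: SimulationConfig, out_dir, tag_id: str = "T001",
                     n_argos_outliers: int = 0) -> TruthRecord:
    """Simulate one shark end to end and write every pipeline input CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_track(config)
    receivers = make_receivers(config)
    detections = simulate_detections(truth, receivers, config, tag_id=tag_id)
    argos = simulate_argos(truth, config, tag_id=tag_id,
                           n_outliers=n_argos_outliers)
    depth_series = simulate_depth_series(
        config, tag_id=tag_id, duration_days=min(config.duration_days, 30))
    tag = make_tag(config, tag_id=tag_id)
    tio.write_receivers(receivers, out_dir / "receivers.csv")
    tio.write_detections(detections, out_dir / "detections.csv")
    tio.write_tags([tag], out_dir / "tags.csv")
    tio.write_argos(argos, out_dir / "argos.csv")
    tio.write_depth_series(depth_series, out_dir / "depth_series.csv")
    write_truth(truth, out_dir)
    return truth
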