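import numpy as np
import pytest

from tigertrack.geo import project_xy
from tigertrack.synthetic import (ConfigError, DiveParams, RegimeParams,
                                  SimulationConfig, detection_probability,
                                  make_bathymetry, make_receivers,
                                  simulate_argos, simulate_depth_series,
                                  simulate_detections, simulate_track)


def _receiver_xy(cfg, receivers):
    return project_xy(np.array([r.lon for r in receivers]),
                      np.array([r.lat for r in receivers]), *cfg.origin)


def test_invalid_configs_raise():
    with pytest.raises(ConfigError):
        SimulationConfig(duration_days=0)
    with pytest.raises(ConfigError):
        SimulationConfig(step_minutes=-5)
    with pytest.raises(ConfigError):
        SimulationConfig(regime="sedentary")
    with pytest.raises(ConfigError):
        SimulationConfig(detection_range_m=(800, 400))
    with pytest.raises(ConfigError):
        SimulationConfig(tag_delay_s=(80, 40))
    with pytest.raises(ConfigError):
        DiveParams(deep_depth_min_m=2000, deep_depth_max_m=100)


def test_same_seed_is_bit_identical():
    a = simulate_track(SimulationConfig(seed=3, duration_days=30))
    b = simulate_track(SimulationConfig(seed=3, duration_days=30))
    assert np.array_equal(a.x_km, b.x_km)
    assert np.array_equal(a.emission_times, b.emission_times)
    c = simulate_track(SimulationConfig(seed=4, duration_days=30))
    assert not np.array_equal(a.x_km, c.x_km)


def test_zero_step_scale_degenerates_to_release_point():
    cfg = SimulationConfig(seed=1, duration_days=5,
                           regime_params=RegimeParams(attraction=0.0,
                                                      step_km=0.0,
                                                      persistence=0.0))
    truth = simulate_track(cfg)
    assert np.allclose(truth.x_km, 0.0) and np.allclose(truth.y_km, 0.0)


def test_resident_stays_near_array():
    """Residents remain within 25 km of the array centroid nearly always."""
    fracs = []
    for seed in range(10):
        truth = simulate_track(SimulationConfig(seed=seed, duration_days=120,
                                                regime="resident"))
        r = np.hypot(truth.x_km, truth.y_km)
        fracs.append((r < 25.0).mean())
    assert min(fracs) >= 0.90


def test_passer_by_leaves_for_good():
    cfg = SimulationConfig(seed=9, duration_days=90, regime="passer_by")
    truth = simulate_track(cfg)
    receivers = make_receivers(cfg)
    rx, ry = _receiver_xy(cfg, receivers)
    after = truth.step_times > 30 * 86400.0
    dist_km = np.min(np.hypot(truth.x_km[after, None] - rx,
                              truth.y_km[after, None] - ry), axis=1)
    assert np.all(dist_km * 1000.0 > cfg.detection_range_m[1])


def test_emission_delays_within_programmed_window():
    cfg = SimulationConfig(seed=2, duration_days=2, tag_delay_s=(40, 80))
    truth = simulate_track(cfg)
    gaps = np.diff(truth.emission_times)
    assert gaps.min() >= 40.0 and gaps.max() <= 80.0
    assert gaps.size > 1000


def test_depths_bounded():
    cfg = SimulationConfig(seed=6, duration_days=30)
    truth = simulate_track(cfg)
    assert truth.depth_m.min() >= 0.0
    assert truth.depth_m.max() <= cfg.dive_params.max_depth_m


def test_no_detection_beyond_max_range():
    cfg = SimulationConfig(seed=8, duration_days=30, regime="transient")
    truth = simulate_track(cfg)
    receivers = make_receivers(cfg)
    simulate_detections(truth, receivers, cfg)
    rx, ry = _receiver_xy(cfg, receivers)
    hit = truth.emission_receiver >= 0
    d_m = 1000.0 * np.hypot(
        truth.emission_x_km[hit] - rx[truth.emission_receiver[hit]],
        truth.emission_y_km[hit] - ry[truth.emission_receiver[hit]])
    assert d_m.size > 0
    assert d_m.max() <= cfg.detection_range_m[1]


def test_out_of_range_shark_never_detected():
    cfg = SimulationConfig(seed=1, duration_days=1,
                           regime_params=RegimeParams(step_km=0.0,
                                                      attraction=0.0))
    truth = simulate_track(cfg)
    truth.emission_x_km[:] = 10.0  # park the shark 10 km off the sole receiver
    truth.emission_y_km[:] = 10.0
    receivers = make_receivers(cfg)[:1]
    assert simulate_detections(truth, receivers, cfg) == []


def test_detection_count_matches_expectation_at_zero_range():
    """A shark parked on a receiver is detected ~ n_emissions * p(0)."""
    counts, expected = [], []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, duration_days=1, tag_delay_s=(40, 80),
                               regime_params=RegimeParams(step_km=0.0,
                                                          attraction=0.0),
                               receiver_layout=[(158.3, -19.9)])
        truth = simulate_track(cfg)  # release point == sole receiver
        receivers = make_receivers(cfg)
        dets = simulate_detections(truth, receivers, cfg)
        counts.append(len(dets))
        expected.append(truth.emission_times.size
                        * detection_probability(0.0, cfg))
    assert abs(np.mean(counts) / np.mean(expected) - 1.0) < 0.10


def test_detection_probability_shape():
    cfg = SimulationConfig()
    rmax = cfg.detection_range_m[1]
    p_half = cfg.detection_p_at_half_range
    assert detection_probability(rmax / 2.0, cfg) == pytest.approx(p_half)
    assert detection_probability(rmax + 1.0, cfg) == 0.0
    d = np.linspace(0, rmax, 50)
    p = detection_probability(d, cfg)
    assert np.all(np.diff(p) <= 1e-12)  # non-increasing in distance


def test_argos_zero_error_recovers_truth():
    cfg = SimulationConfig(seed=5, duration_days=10,
                           argos_error_m={c: 1e-9 for c in "321" "0AB"},
                           argos_class_mix={"3": 1.0})
    truth = simulate_track(cfg)
    fixes = simulate_argos(truth, cfg)
    tx = np.interp(truth.argos_truth.time_s, truth.step_times, truth.x_km)
    x, _ = project_xy(np.array([f.lon for f in fixes]),
                      np.array([f.lat for f in fixes]), *cfg.origin)
    assert np.allclose(x, tx, atol=1e-5)


def test_argos_class3_median_error_is_rayleigh_like():
    """Median 2D displacement for a 250 m scale lies in [150, 350] m."""
    cfg = SimulationConfig(seed=12, duration_days=100, argos_per_day=10.0,
                           argos_class_mix={"3": 1.0})
    truth = simulate_track(cfg)
    fixes = simulate_argos(truth, cfg)
    x, y = project_xy(np.array([f.lon for f in fixes]),
                      np.array([f.lat for f in fixes]), *cfg.origin)
    tx = np.interp(truth.argos_truth.time_s, truth.step_times, truth.x_km)
    ty = np.interp(truth.argos_truth.time_s, truth.step_times, truth.y_km)
    med_m = 1000.0 * np.median(np.hypot(x - tx, y - ty))
    assert 150.0 <= med_m <= 350.0


def test_argos_outliers_flagged():
    cfg = SimulationConfig(seed=7, duration_days=30)
    truth = simulate_track(cfg)
    simulate_argos(truth, cfg, n_outliers=5, outlier_offset_km=500.0)
    assert truth.argos_truth.is_outlier.sum() == 5
    assert (truth.argos_truth.loc[truth.argos_truth.is_outlier,
                                  "loc_class"] == "B").all()


def test_depth_series_two_modes():
    cfg = SimulationConfig(seed=3)
    # no deep dives: bounded by the shallow mode
    quiet = DiveParams(deep_rate_per_day=0.0)
    series = simulate_depth_series(SimulationConfig(seed=3, dive_params=quiet),
                                   duration_days=5)
    assert max(r.depth_m for r in series) <= quiet.shallow_max_m
    # point-mass deep dives hit exactly the configured depth
    deep = DiveParams(deep_depth_min_m=1136.0, deep_depth_max_m=1136.0,
                      deep_rate_per_day=3.0)
    series = simulate_depth_series(SimulationConfig(seed=4, dive_params=deep),
                                   duration_days=10)
    assert max(r.depth_m for r in series) == pytest.approx(1136.0)


def test_temperature_decreases_with_depth():
    dp = DiveParams()
    d = np.linspace(0, 1200, 100)
    t = dp.temp_at_depth(d)
    assert np.all(np.diff(t) < 0)
    series = simulate_depth_series(SimulationConfig(seed=5), duration_days=3)
    shallow = [r.temp_c for r in series if r.depth_m < 20]
    deep = [r.temp_c for r in series if r.depth_m > 500]
    if deep:
        assert np.mean(deep) < np.mean(shallow)


def test_bathymetry_grids():
    flat = make_bathymetry((158.0, 158.5, -20.0, -19.5), 10.0,
                           lambda lon, lat: np.full_like(lon, 2000.0))
    assert np.all(flat.seafloor_depth_m == 2000.0)
    shelf = make_bathymetry((158.0, 159.0, -20.0, -19.5), 5.0,
                            lambda lon, lat: 1.0 + 2000.0 * (lon - 158.0))
    mid = shelf.depth_at(158.5, -19.75)
    assert mid == pytest.approx(1001.0, rel=0.05)
    with pytest.raises(ConfigError):
        make_bathymetry((158.0, 158.5, -20.0, -19.5), 10.0,
                        lambda lon, lat: np.full_like(lon, np.nan))
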