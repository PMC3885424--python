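import numpy as np
import pandas as pd
import pytest

from tigertrack.geo import unproject_xy
from tigertrack.synthetic import make_bathymetry
from tigertrack.tracks import (bathymetric_correct, corrected_track,
                               depth_temp_summary, displacement_from_release)
from tigertrack.types import DepthTempRecord, TrackPoint
from conftest import T0

ORIGIN = (158.3, -19.9)


def _point(day, x_km, y_km=0.0, depth=None, ci=None, tag="T001"):
    lon, lat = unproject_xy(float(x_km), float(y_km), *ORIGIN)
    return TrackPoint(tag, (T0 + pd.Timedelta(days=day)).normalize(),
                      float(lon), float(lat), ci_radius_km=ci,
                      max_daily_depth_m=depth)


def shelf_grid():
    """100 m shelf west of 158.5 E, 2000 m basin east of it."""
    return make_bathymetry((157.8, 159.2, -20.4, -19.4), 4.0,
                           lambda lon, lat: np.where(lon < 158.5, 100.0, 2000.0))


class TestBathymetricCorrection:
    def test_zero_dive_depth_leaves_track_unchanged(self):
        track = [_point(i, 5.0 * i, depth=0.0) for i in range(5)]
        corr = bathymetric_correct(track, shelf_grid())
        assert all(not c.moved and not c.infeasible for c in corr)
        assert corrected_track(corr) == track

    def test_deep_dive_relocates_to_basin(self):
        """A 1136 m dive over the 100 m shelf moves east to deep water."""
        track = [_point(0, 0.0, depth=1136.0)]  # on the shelf
        corr = bathymetric_correct(track, shelf_grid(), search_radius_km=100.0)
        assert corr[0].moved and not corr[0].infeasible
        moved = corr[0].point
        assert moved.lon > 158.5  # pushed into the basin
        grid = shelf_grid()
        assert float(grid.depth_at(moved.lon, moved.lat)) >= 1136.0

    def test_all_cells_too_shallow_flags_infeasible(self):
        grid = make_bathymetry((158.0, 158.6, -20.2, -19.6), 5.0,
                               lambda lon, lat: np.full_like(lon, 300.0))
        track = [_point(0, 0.0, depth=900.0)]
        corr = bathymetric_correct(track, grid)
        assert corr[0].infeasible and not corr[0].moved
        assert corr[0].point == track[0]

    def test_correction_is_idempotent(self):
        track = [_point(0, 0.0, depth=1136.0), _point(1, 30.0, depth=50.0)]
        once = corrected_track(bathymetric_correct(track, shelf_grid()))
        twice = corrected_track(bathymetric_correct(once, shelf_grid()))
        assert once == twice

    def test_displacement_bounded_by_search_radius(self):
        track = [_point(0, 0.0, depth=1136.0)]
        corr = bathymetric_correct(track, shelf_grid(), search_radius_km=60.0)
        if corr[0].moved:
            assert corr[0].displacement_km <= 60.0 + 1e-9

    def test_ci_radius_caps_search(self):
        track = [_point(0, -40.0, depth=1136.0, ci=5.0)]  # basin ~75 km east
        corr = bathymetric_correct(track, shelf_grid(), search_radius_km=200.0)
        assert corr[0].infeasible  # nothing deep enough within 5 km

    def test_track_outside_grid_errors(self):
        track = [_point(0, 500.0)]
        with pytest.raises(ValueError, match="outside"):
            bathymetric_correct(track, shelf_grid())


class TestDisplacement:
    def test_release_point_only_is_zero(self):
        track = [_point(0, 0.0)]
        assert displacement_from_release(track, ORIGIN) == pytest.approx(0.0,
                                                                         abs=1e-9)

    def test_straight_transit_1141_km(self):
        track = [_point(i, 1141.0 * i / 20.0) for i in range(21)]
        d = displacement_from_release(track, ORIGIN)
        assert d == pytest.approx(1141.0, rel=1e-3)

    def test_order_free(self):
        track = [_point(i, x) for i, x in enumerate([0, 50, 20, 80, 10])]
        d1 = displacement_from_release(track, ORIGIN)
        d2 = displacement_from_release(list(reversed(track)), ORIGIN)
        assert d1 == d2

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            displacement_from_release([], ORIGIN)


def _rec(depth, temp, i=0, tag="T001"):
    return DepthTempRecord(tag, T0 + pd.Timedelta(minutes=10 * i),
                           float(depth), float(temp))


class TestDepthTempSummary:
    def test_constant_series(self):
        s = depth_temp_summary([_rec(40.0, 25.0, i) for i in range(10)])
        assert s.max_depth_m == s.mean_depth_m == 40.0
        assert s.modal_depth_m == 40.0

    def test_two_mode_series_modal_at_shallow_mode(self):
        """Dominant 40 m occupancy -> modal depth 40.0 despite deep dives."""
        rng = np.random.default_rng(0)
        recs = [_rec(40.0 + rng.uniform(-0.2, 0.2), 24.0, i)
                for i in range(200)]
        recs += [_rec(d, 8.0, 200 + i)
                 for i, d in enumerate(rng.uniform(400, 1100, 30))]
        s = depth_temp_summary(recs)
        assert s.modal_depth_m == pytest.approx(40.0)
        assert s.max_depth_m > 400

    def test_mean_matches_direct_average(self):
        rng = np.random.default_rng(1)
        depths = rng.uniform(0, 800, 1000)
        temps = rng.uniform(5, 28, 1000)
        s = depth_temp_summary([_rec(d, t, i)
                                for i, (d, t) in enumerate(zip(depths, temps))])
        assert s.mean_depth_m == pytest.approx(depths.mean())
        assert s.mean_temp_c == pytest.approx(temps.mean())
        assert s.min_temp_c <= s.mean_temp_c <= s.max_temp_c

    def test_order_invariance(self):
        recs = [_rec(d, 20.0, i) for i, d in enumerate([10, 20, 20, 30])]
        a = depth_temp_summary(recs)
        b = depth_temp_summary(list(reversed(recs)))
        assert a.modal_depth_m == b.modal_depth_m
        assert a.mean_depth_m == b.mean_depth_m

    def test_modal_tie_breaks_shallow(self):
        recs = [_rec(10.0, 20.0, 0), _rec(10.0, 20.0, 1),
                _rec(50.0, 20.0, 2), _rec(50.0, 20.0, 3)]
        assert depth_temp_summary(recs).modal_depth_m == 10.0

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            depth_temp_summary([])
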