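"""Geodesy, speed filtering, trip segmentation and trip metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_minimal_removal, law_of_cosines_km
from shearwater.track import (Trip, daily_wind_means, great_circle_km,
                              initial_bearing, position_at, segment_trips,
                              speed_filter, track_speeds_kmh, trip_metrics)

COLONY = (-37.56, 149.91)


def make_track(lats, lons, step_s=300):
    n = len(lats)
    ts = pd.date_range("2012-02-10", periods=n, freq=f"{step_s}s", tz="UTC")
    return pd.DataFrame({"timestamp": ts, "lat": lats, "lon": lons})


class TestGreatCircle:
    def test_zero_for_coincident_points(self):
        assert great_circle_km((-38.0, 142.0), (-38.0, 142.0)) == 0.0

    def test_one_degree_of_latitude(self):
        # closed form: 2*pi*R/360
        d = great_circle_km((10.0, 30.0), (11.0, 30.0))
        assert d == pytest.approx(2 * math.pi * 6371.0 / 360.0, abs=1e-6)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            a = (rng.uniform(-80, 80), rng.uniform(-180, 180))
            b = (a[0] + rng.uniform(-5, 5), a[1] + rng.uniform(-5, 5))
            assert great_circle_km(a, b) == pytest.approx(
                law_of_cosines_km(a, b), abs=1e-3)  # 1 m

    @given(st.floats(-80, 80), st.floats(-179, 179),
           st.floats(-80, 80), st.floats(-179, 179))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, la1, lo1, la2, lo2):
        d1 = great_circle_km((la1, lo1), (la2, lo2))
        d2 = great_circle_km((la2, lo2), (la1, lo1))
        assert d1 >= 0
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestBearing:
    def test_due_north_is_zero(self):
        assert initial_bearing((-38.0, 142.0), (-37.0, 142.0)) == pytest.approx(0.0)

    def test_due_east_on_equator_is_90(self):
        assert initial_bearing((0.0, 10.0), (0.0, 11.0)) == pytest.approx(90.0)

    def test_forward_reverse_differ_by_180_on_meridian(self):
        f = initial_bearing((10.0, 20.0), (12.0, 20.0))
        r = initial_bearing((12.0, 20.0), (10.0, 20.0))
        assert (r - f) % 360.0 == pytest.approx(180.0)

    def test_coincident_points_error(self):
        with pytest.raises(ValueError):
            initial_bearing((1.0, 1.0), (1.0, 1.0))


class TestSpeedFilter:
    def teleport(self, track, idx, km=25.0):
        out = track.copy()
        out.loc[idx, "lat"] = out.loc[idx, "lat"] + km / 111.2
        return out

    def clean_track(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        # random walk at < 40 km/h between 5-min fixes (steps < 3.3 km)
        steps = rng.uniform(0.5, 3.0, n - 1)
        brg = np.cumsum(rng.normal(0, 20, n - 1))
        lat = [COLONY[0]]
        lon = [COLONY[1]]
        for s, b in zip(steps, brg):
            lat.append(lat[-1] + s * math.cos(math.radians(b)) / 111.2)
            lon.append(lon[-1] + s * math.sin(math.radians(b))
                       / (111.2 * math.cos(math.radians(lat[-1]))))
        return make_track(lat, lon)

    def test_clean_track_untouched(self):
        track = self.clean_track()
        filtered, removed = speed_filter(track)
        assert removed == []
        assert len(filtered) == len(track)

    def test_single_teleport_removed_exactly(self):
        track = self.teleport(self.clean_track(), 10)
        filtered, removed = speed_filter(track)
        assert removed == [10]
        assert (track_speeds_kmh(filtered) <= 60).all()

    def test_idempotent_and_endpoints_kept(self):
        track = self.teleport(self.teleport(self.clean_track(), 10), 25)
        filtered, removed = speed_filter(track)
        again, removed2 = speed_filter(filtered)
        assert removed2 == []
        assert filtered["timestamp"].iloc[0] == track["timestamp"].iloc[0]
        assert filtered["timestamp"].iloc[-1] == track["timestamp"].iloc[-1]

    def test_matches_bruteforce_minimal_removal_on_small_tracks(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(5, 11))
            track = self.clean_track(n=n, seed=100 + trial)
            n_out = int(rng.integers(1, 3))
            idx = sorted(rng.choice(range(1, n - 1), size=min(n_out, n - 2),
                                    replace=False))
            for i in idx:
                track = self.teleport(track, int(i), km=rng.uniform(15, 40))
            filtered, removed = speed_filter(track)
            oracle = brute_force_minimal_removal(track, 60.0)
            assert (track_speeds_kmh(filtered) <= 60).all()
            assert len(removed) == len(oracle)

    def test_rejects_bad_vmax(self):
        with pytest.raises(ValueError):
            speed_filter(self.clean_track(), vmax=0)


class TestSegmentTrips:
    def out_and_back(self, start_idx=2, n_out=6):
        """Fixes at the colony, an excursion, then back at the colony."""
        lat = [COLONY[0]] * start_idx
        for i in range(1, n_out + 1):
            lat.append(COLONY[0] + 0.02 * i)
        for i in range(n_out - 1, 0, -1):
            lat.append(COLONY[0] + 0.02 * i)
        lat += [COLONY[0]] * 2
        lon = [COLONY[1]] * len(lat)
        return make_track(lat, lon)

    def test_track_inside_radius_yields_no_trips(self):
        track = make_track([COLONY[0]] * 5, [COLONY[1]] * 5)
        assert segment_trips(track, COLONY, 1.0) == []

    def test_single_excursion_yields_one_complete_trip(self):
        trips = segment_trips(self.out_and_back(), COLONY, 1.0)
        assert len(trips) == 1
        assert trips[0].complete

    def test_two_excursions_with_colony_visit_between(self):
        t1 = self.out_and_back()
        t2 = self.out_and_back()
        t2["timestamp"] = t2["timestamp"] + pd.Timedelta(hours=4)
        track = pd.concat([t1, t2], ignore_index=True)
        trips = [t for t in segment_trips(track, COLONY, 1.0) if t.complete]
        assert len(trips) == 2

    def test_edge_truncated_excursion_flagged_incomplete(self):
        track = self.out_and_back().iloc[4:].reset_index(drop=True)
        trips = segment_trips(track, COLONY, 1.0)
        assert len(trips) == 1
        assert not trips[0].complete

    def test_simulated_dataset_one_trip(self, sim16):
        filtered, _ = speed_filter(sim16.gps)
        trips = [t for t in segment_trips(filtered, sim16.config.colony, 1.0)
                 if t.complete]
        assert len(trips) == 1


class TestTripMetrics:
    def test_stationary_two_fix_trip(self):
        ts = pd.to_datetime(["2012-02-10 00:00", "2012-02-10 01:00"], utc=True)
        fixes = pd.DataFrame({"timestamp": ts,
                              "lat": [COLONY[0]] * 2, "lon": [COLONY[1]] * 2})
        m = trip_metrics(Trip(fixes, COLONY))
        assert m.duration_h == pytest.approx(1.0)
        assert m.total_distance_km == pytest.approx(0.0)
        assert m.max_distance_km == pytest.approx(0.0)

    def test_total_distance_close_to_simulated_path(self, sim16, trip16):
        m = trip_metrics(trip16)
        # 5-min sampling undershoots the integrated path; within a few %
        assert m.total_distance_km <= sim16.truth_path_km
        assert m.total_distance_km == pytest.approx(sim16.truth_path_km, rel=0.10)
        assert m.avg_speed_kmh == pytest.approx(
            m.total_distance_km / m.duration_h)

    def test_total_distance_invariant_under_reversal(self, trip16):
        rev = trip16.fixes.iloc[::-1].reset_index(drop=True)
        span = trip16.fixes["timestamp"]
        rev["timestamp"] = span.iloc[0] + (span.iloc[-1] - span.iloc[::-1].reset_index(drop=True))
        m1 = trip_metrics(trip16)
        m2 = trip_metrics(Trip(rev, trip16.colony))
        assert m2.total_distance_km == pytest.approx(m1.total_distance_km)


class TestDailyWindMeans:
    def wind(self, directions, speeds, day="2012-02-10"):
        ts = pd.date_range(day, periods=len(directions), freq="3h", tz="UTC")
        return pd.DataFrame({"timestamp": ts, "speed": speeds,
                             "direction": directions})

    def test_constant_wind_unchanged(self):
        w = daily_wind_means(self.wind([90.0] * 8, [5.0] * 8))
        assert len(w) == 1
        assert w["speed"].iloc[0] == pytest.approx(5.0)
        assert w["direction"].iloc[0] == pytest.approx(90.0)

    def test_circular_mean_wraps_north(self):
        w = daily_wind_means(self.wind([350.0, 10.0], [5.0, 5.0]))
        assert w["direction"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(1)
        dirs = rng.uniform(0, 360, 8)
        spds = rng.uniform(0, 15, 8)
        w = daily_wind_means(self.wind(dirs, spds))
        rad = np.radians(dirs)
        expect = math.degrees(math.atan2(np.mean(np.sin(rad)),
                                         np.mean(np.cos(rad)))) % 360.0
        assert w["direction"].iloc[0] == pytest.approx(expect)
        assert w["speed"].iloc[0] == pytest.approx(spds.mean())


class TestPositionAt:
    def trip(self):
        ts = pd.date_range("2012-02-10", periods=3, freq="300s", tz="UTC")
        fixes = pd.DataFrame({"timestamp": ts,
                              "lat": [-37.5, -37.45, -37.45],
                              "lon": [149.9, 149.9, 149.95]})
        return Trip(fixes, COLONY)

    def test_fix_time_returns_fix(self):
        t = self.trip()
        la, lo = position_at(t, t.fixes["timestamp"].iloc[1])
        assert la == pytest.approx(-37.45, abs=1e-9)
        assert lo == pytest.approx(149.9, abs=1e-9)

    def test_midpoint_close_to_flat_earth_midpoint(self):
        t = self.trip()
        mid = t.fixes["timestamp"].iloc[0] + pd.Timedelta(seconds=150)
        la, lo = position_at(t, mid)
        # < 10 km segment: slerp vs planar midpoint agree within metres
        assert great_circle_km((la, lo), (-37.475, 149.9)) < 0.005

    def test_distance_from_start_monotone(self):
        t = self.trip()
        t0 = t.fixes["timestamp"].iloc[0]
        p0 = (t.fixes["lat"].iloc[0], t.fixes["lon"].iloc[0])
        dists = [great_circle_km(position_at(t, t0 + pd.Timedelta(seconds=s)), p0)
                 for s in range(0, 301, 30)]
        assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_outside_span_raises(self):
        t = self.trip()
        with pytest.raises(ValueError):
            position_at(t, t.fixes["timestamp"].iloc[0] - pd.Timedelta(seconds=1))
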