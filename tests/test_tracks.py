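import numpy as np
import pandas as pd
import pytest

from foragescape.geo import great_circle_km
from foragescape.simulate import single_patch_config, simulate_trajectory
from foragescape.tracks import (TrackFormatError, TrackValidationError,
                                Trajectory, classify_behaviour, read_tracks,
                                segment_trips, trip_metrics)

from conftest import KM_PER_DEG

COLONY = (-24.5877, 16.6113)


def _write_csv(tmp_path, rows, columns=("individual_id", "timestamp", "lon", "lat")):
    path = tmp_path / "tracks.csv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


class TestReadTracks:
    def test_well_formed_table_gives_one_trajectory(self, tmp_path):
        path = _write_csv(tmp_path, [
            ("b1", "2014-06-01T00:00:00Z", -24.0, 16.0),
            ("b1", "2014-06-01T00:05:00Z", -24.1, 16.0),
            ("b1", "2014-06-01T00:10:00Z", -24.2, 16.0)])
        trajs = read_tracks(path, COLONY)
        assert len(trajs) == 1 and trajs[0].n_fixes == 3
        assert trajs[0].individual_id == "b1"

    def test_rows_out_of_order_are_time_sorted(self, tmp_path):
        path = _write_csv(tmp_path, [
            ("b1", "2014-06-01T00:05:00Z", -24.1, 16.0),
            ("b1", "2014-06-01T00:00:00Z", -24.0, 16.0)])
        (traj,) = read_tracks(path, COLONY)
        assert traj.fixes["lon"].tolist() == [-24.0, -24.1]
        assert traj.fixes["timestamp"].is_monotonic_increasing

    def test_missing_column_is_a_format_error(self, tmp_path):
        path = _write_csv(tmp_path, [("b1", "2014-06-01T00:00:00Z", -24.0)],
                          columns=("individual_id", "timestamp", "lon"))
        with pytest.raises(TrackFormatError, match="lat"):
            read_tracks(path, COLONY)

    def test_duplicate_timestamp_names_individual(self, tmp_path):
        path = _write_csv(tmp_path, [
            ("b2", "2014-06-01T00:00:00Z", -24.0, 16.0),
            ("b2", "2014-06-01T00:00:00Z", -24.1, 16.0)])
        with pytest.raises(TrackValidationError, match="b2"):
            read_tracks(path, COLONY)


class TestGreatCircle:
    def test_coincident_points_give_zero(self):
        assert great_circle_km(0, 0, 0, 0) == 0.0

    def test_one_degree_arc_at_equator(self):
        assert great_circle_km(0, 0, 1, 0) == pytest.approx(
            6371.0088 * np.pi / 180, rel=1e-12)

    def test_symmetry_on_random_pairs(self, rng):
        lons = rng.uniform(-180, 180, size=(100, 2))
        lats = rng.uniform(-85, 85, size=(100, 2))
        d1 = great_circle_km(lons[:, 0], lats[:, 0], lons[:, 1], lats[:, 1])
        d2 = great_circle_km(lons[:, 1], lats[:, 1], lons[:, 0], lats[:, 0])
        assert np.allclose(d1, d2)
        assert (d1 >= 0).all()


def _speed_trajectory(speeds_kmh):
    """One fix every hour, due east, leg lengths chosen to match speeds."""
    lon = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_kmh) / KM_PER_DEG)])
    t = pd.date_range("2014-06-01", periods=len(lon), freq="1h", tz="UTC")
    return Trajectory("b", (0.0, 0.0),
                      pd.DataFrame({"timestamp": t, "lon": lon,
                                    "lat": np.zeros(len(lon))}))


class TestClassifyBehaviour:
    def test_below_threshold_is_rest_at_it_is_flight(self):
        traj = classify_behaviour(_speed_trajectory([2.9, 3.0, 10.0]))
        assert traj.fixes["behaviour"].tolist()[1:] == ["rest", "flight", "flight"]

    def test_first_fix_inherits_second(self):
        traj = classify_behaviour(_speed_trajectory([2.0, 10.0]))
        assert traj.fixes["behaviour"].iloc[0] == "rest"

    def test_constant_fast_path_is_all_flight(self):
        traj = classify_behaviour(_speed_trajectory([10.0] * 5))
        assert (traj.fixes["behaviour"] == "flight").all()

    def test_single_fix_is_an_error(self):
        single = Trajectory("b", (0.0, 0.0), _speed_trajectory([5.0]).fixes.iloc[:1])
        with pytest.raises(TrackValidationError):
            classify_behaviour(single)


class TestSegmentTrips:
    def _excursion_trajectory(self):
        # out 50 km, dwell, back: one clean excursion of ~6 h
        km = [0, 0.5, 10, 25, 40, 50, 50, 50, 40, 25, 10, 0.5, 0]
        lon = np.asarray(km) / KM_PER_DEG
        t = pd.date_range("2014-06-01", periods=len(lon), freq="30min", tz="UTC")
        return Trajectory("b", (0.0, 0.0),
                          pd.DataFrame({"timestamp": t, "lon": lon,
                                        "lat": np.zeros(len(lon))}))

    def test_single_excursion_gives_one_trip(self):
        trips = segment_trips(self._excursion_trajectory())
        assert len(trips) == 1
        assert trips[0].fixes["lon"].max() * KM_PER_DEG == pytest.approx(50)

    def test_never_leaving_buffer_gives_no_trips(self):
        lon = np.array([0.0, 0.5, 0.9, 0.3]) / KM_PER_DEG
        t = pd.date_range("2014-06-01", periods=4, freq="1h", tz="UTC")
        traj = Trajectory("b", (0.0, 0.0),
                          pd.DataFrame({"timestamp": t, "lon": lon,
                                        "lat": np.zeros(4)}))
        assert segment_trips(traj) == []

    def test_simulator_excursion_count_is_recovered(self):
        cfg = single_patch_config(seed=4, n_excursions=5)
        traj, truth = simulate_trajectory(cfg)
        trips = segment_trips(classify_behaviour(traj))
        assert truth["n_excursions"] == 5
        assert len(trips) == 5

    def test_segmentation_is_idempotent(self):
        (trip,) = segment_trips(self._excursion_trajectory())
        again = segment_trips(
            Trajectory("b", (0.0, 0.0), trip.fixes))
        assert len(again) == 1
        pd.testing.assert_frame_equal(again[0].fixes, trip.fixes)


class TestTripMetrics:
    def test_total_distance_is_additive(self):
        # 4 legs of exactly 100 km: out 200 km and back
        km = [2.5, 102.5, 202.5, 102.5, 2.5]
        lon = np.asarray(km) / KM_PER_DEG
        t = pd.date_range("2014-06-01", periods=5, freq="2h", tz="UTC")
        trip = segment_trips(Trajectory("b", (0.0, 0.0), pd.DataFrame(
            {"timestamp": t, "lon": lon, "lat": np.zeros(5)})))[0]
        m = trip_metrics(trip)
        assert m["total_distance_km"] == pytest.approx(400.0, rel=1e-5)
        assert m["max_distance_colony_km"] == pytest.approx(202.5, rel=1e-5)

    @pytest.mark.parametrize("days,expected", [(3.0, "short"), (3.1, "long")])
    def test_three_day_rule_is_strict(self, days, expected):
        n = 7
        t = pd.date_range("2014-06-01", periods=n, tz="UTC",
                          freq=pd.Timedelta(days=days / (n - 1)))
        lon = np.array([0.1, 0.2, 0.3, 0.4, 0.3, 0.2, 0.1])
        trip = segment_trips(Trajectory("b", (0.0, 0.0), pd.DataFrame(
            {"timestamp": t, "lon": lon, "lat": np.zeros(n)})))[0]
        assert trip_metrics(trip)["duration_class"] == expected

    def test_flight_hours_per_day_for_all_flight_trip(self):
        trip = segment_trips(classify_behaviour(_speed_trajectory([20.0] * 48)))[0]
        m = trip_metrics(trip)
        # continuous flight: close to 24 h/day (edge fixes carry half gaps)
        assert m["flight_hours_per_day"] == pytest.approx(24.0, rel=0.05)

    def test_trip_distances_bounded_by_trajectory_path(self):
        cfg = single_patch_config(seed=9, n_excursions=2)
        traj, _ = simulate_trajectory(cfg)
        traj = classify_behaviour(traj)
        lon, lat = traj.fixes["lon"].to_numpy(), traj.fixes["lat"].to_numpy()
        total_path = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:]).sum()
        trips = segment_trips(traj)
        per_trip = sum(trip_metrics(t)["total_distance_km"] for t in trips)
        assert per_trip <= total_path + 1e-9
        classes = {trip_metrics(t)["duration_class"] for t in trips}
        assert classes <= {"short", "long"}
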