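import math

import numpy as np
import pandas as pd
import pytest

from foragescape.fpt import (COARSE_RADII_KM, MESO_RADII_KM, FptProfile,
                             delineate_ars_zones, detect_ars_scale,
                             first_passage_time, interpolate_path,
                             two_stage_ars, variance_profile)
from foragescape.simulate import single_patch_config, simulate_trajectory
from foragescape.tracks import classify_behaviour, segment_trips

from conftest import straight_trip, trip_from_xy


# ---------------------------------------------------------------------------
# independent brute-force oracle: walk every segment, bisect the crossing

def oracle_fpt(xy, t_h, i, r):
    """First-passage time at vertex i for radius r by explicit path walking."""
    cx, cy = xy[i]

    def dist(p):
        return math.hypot(p[0] - cx, p[1] - cy)

    def one_direction(indices):
        prev = None
        for j in indices:
            if dist(xy[j]) > r:
                assert prev is not None
                # bisection for |p(a)+(p(b)-p(a))s - c| = r on the segment
                a, b = prev, j
                lo, hi = 0.0, 1.0
                pa, pb = xy[a], xy[b]
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    p = (pa[0] + (pb[0] - pa[0]) * mid,
                         pa[1] + (pb[1] - pa[1]) * mid)
                    if dist(p) > r:
                        hi = mid
                    else:
                        lo = mid
                s = 0.5 * (lo + hi)
                return abs((t_h[a] + s * (t_h[b] - t_h[a])) - t_h[i])
            prev = j
        return None

    fwd = one_direction(range(i, len(xy)))
    bwd = one_direction(range(i, -1, -1))
    if fwd is None or bwd is None:
        return None
    return fwd + bwd


def random_path(rng, n):
    """CRW-like planar path with variable speeds (km, hours)."""
    steps = rng.gamma(2.0, 1.0, size=n - 1)
    theta = np.cumsum(rng.vonmises(0.0, 1.5, size=n - 1))
    xy = np.vstack([[0.0, 0.0],
                    np.cumsum(np.column_stack([steps * np.cos(theta),
                                               steps * np.sin(theta)]), axis=0)])
    t = np.concatenate([[0.0], np.cumsum(rng.gamma(3.0, 0.05, size=n - 1))])
    return xy, t


class _PathStub:
    """Minimal InterpolatedPath stand-in for direct FPT calls."""

    def __init__(self, xy, t_h):
        self.xy = np.asarray(xy, dtype=float)
        self.t_h = np.asarray(t_h, dtype=float)


class TestInterpolation:
    def test_one_km_leg_at_tenth_km_step_gives_11_vertices(self):
        trip = straight_trip(length_km=1.0, fix_km=1.0)
        path = interpolate_path(trip, 0.1)
        assert path.n_vertices == 11

    def test_endpoints_are_preserved(self):
        trip = straight_trip(length_km=10.0)
        path = interpolate_path(trip, 0.3)
        lon, lat = path.lonlat()
        assert lon[0] == pytest.approx(trip.fixes["lon"].iloc[0], abs=1e-9)
        assert lon[-1] == pytest.approx(trip.fixes["lon"].iloc[-1], abs=1e-9)

    def test_constant_speed_gives_equally_spaced_times(self):
        path = interpolate_path(straight_trip(length_km=10.0), 0.5)
        assert np.allclose(np.diff(path.t_h), np.diff(path.t_h)[0], rtol=1e-6)

    def test_rest_bouts_are_removed_and_path_reconnected(self):
        trip = straight_trip(length_km=10.0)
        trip.fixes.loc[4:6, "behaviour"] = "rest"
        path = interpolate_path(trip, 0.5)
        # the rectified path skips the 3 resting fixes: length shrinks by the
        # two legs replaced by one reconnection jump of 3 km -> no change in
        # along-path distance here (collinear), but vertex count stays finite
        assert path.length_km == pytest.approx(10.0 - 3.0 + 3.0, abs=0.5)

    def test_too_few_flight_fixes_is_an_error(self):
        trip = straight_trip(length_km=5.0)
        trip.fixes["behaviour"] = "rest"
        with pytest.raises(ValueError):
            interpolate_path(trip, 0.1)


class TestFirstPassageTime:
    def test_straight_path_matches_2r_over_v(self):
        path = interpolate_path(straight_trip(speed_kmh=10.0, length_km=50.0),
                                0.1)
        fpt = first_passage_time(path, 5.0)
        interior = fpt[np.isfinite(fpt)]
        assert np.allclose(interior, 1.0, rtol=0.01)

    def test_vertices_near_ends_are_undefined(self):
        path = interpolate_path(straight_trip(length_km=50.0), 0.5)
        fpt = first_passage_time(path, 5.0)
        assert np.isnan(fpt[0]) and np.isnan(fpt[-1])
        assert np.isnan(fpt[:9]).all() and np.isnan(fpt[-9:]).all()

    def test_direction_reversal_invariance(self, rng):
        xy, t = random_path(rng, 150)
        fwd = first_passage_time(_PathStub(xy, t), 3.0)
        # reversed path with reversed (still increasing) times
        rev = first_passage_time(_PathStub(xy[::-1], t[-1] - t[::-1]), 3.0)
        assert np.allclose(fwd, rev[::-1], rtol=1e-9, equal_nan=True)

    def test_matches_brute_force_oracle_on_random_paths(self, rng):
        for _ in range(5):
            n = int(rng.integers(60, 220))
            xy, t = random_path(rng, n)
            radii = np.sort(rng.uniform(0.5, 8.0, size=2))
            fpt = first_passage_time(_PathStub(xy, t), radii)
            for k, r in enumerate(radii):
                for i in range(0, n, 7):
                    expected = oracle_fpt(xy, t, i, r)
                    if expected is None:
                        assert np.isnan(fpt[i, k])
                    else:
                        assert fpt[i, k] == pytest.approx(expected, rel=1e-9)


class TestVarianceProfile:
    def test_straight_path_has_negligible_variance(self):
        path = interpolate_path(straight_trip(length_km=100.0), 1.0)
        prof = variance_profile(path, np.array([2.0, 5.0, 10.0]))
        assert np.nanmax(prof.var_log_fpt) < 1e-6

    def test_speed_rescaling_leaves_variance_unchanged(self, rng):
        xy, t = random_path(rng, 200)
        radii = np.array([1.0, 2.0, 4.0])
        v1 = variance_profile(_PathStub(xy, t), radii).var_log_fpt
        v2 = variance_profile(_PathStub(xy, t * 3.0), radii).var_log_fpt
        assert np.allclose(v1, v2, rtol=1e-9, equal_nan=True)

    def test_matches_plain_recomputation(self, rng):
        xy, t = random_path(rng, 150)
        radii = np.array([1.0, 3.0])
        prof = variance_profile(_PathStub(xy, t), radii)
        fpt = first_passage_time(_PathStub(xy, t), radii)
        for k in range(len(radii)):
            vals = [math.log(v) for v in fpt[:, k] if np.isfinite(v)]
            if len(vals) >= 2:
                mean = sum(vals) / len(vals)
                var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
                assert prof.var_log_fpt[k] == pytest.approx(var, rel=1e-9)


def _profile(radii, var):
    return FptProfile(radii=np.asarray(radii, dtype=float),
                      fpt=np.zeros((1, len(radii))),
                      var_log_fpt=np.asarray(var, dtype=float),
                      n_defined=np.full(len(radii), 5))


class TestScaleDetection:
    def test_unimodal_peak_is_read_off(self):
        radii = np.arange(1, 41)
        var = np.exp(-0.5 * ((radii - 20) / 6.0) ** 2)
        assert detect_ars_scale(_profile(radii, var)) == 20

    def test_monotone_profile_is_rejected(self):
        radii = np.arange(1, 21)
        assert detect_ars_scale(_profile(radii, radii * 0.1)) is None

    def test_tie_breaks_toward_smaller_radius(self):
        radii = np.arange(1, 11)
        var = np.array([0.1, 0.2, 0.3, 0.2, 0.9, 0.3, 0.2, 0.3, 0.9, 0.1])
        # equal maxima at radii 5 and 9 -> 5
        assert detect_ars_scale(_profile(radii, var)) == 5


class TestZoneDelineation:
    def test_straight_path_yields_no_zones(self):
        path = interpolate_path(straight_trip(length_km=100.0), 1.0)
        # uniform FPT: no vertex exceeds the 0.75-quantile materially
        zones = delineate_ars_zones(path, 5.0)
        for z in zones:
            assert z.residence_h < 0.5  # nothing resembling a patch

    def test_single_patch_zone_centred_on_the_patch(self):
        hits = 0
        for seed in range(5):
            cfg = single_patch_config(seed, n_excursions=1)
            traj, truth = simulate_trajectory(cfg)
            trip = segment_trips(classify_behaviour(traj))[0]
            path = interpolate_path(trip, 1.0)
            prof = variance_profile(path, MESO_RADII_KM)
            scale = detect_ars_scale(prof)
            if scale is None:
                continue
            zones = delineate_ars_zones(path, scale)
            assert zones, "a foraging trip must contain at least one ARS zone"
            main = max(zones, key=lambda z: z.residence_h)
            from foragescape.geo import great_circle_km
            patch = truth["patches"][0]
            plon, plat = path.proj.inverse(*patch["center_km"])
            if great_circle_km(main.center_lon, main.center_lat,
                               plon, plat) < patch["radius_km"]:
                hits += 1
        assert hits >= 4

    def test_two_separated_patches_give_two_zones_in_entry_order(self):
        # synthetic FPT path: slow dwell at 40 km and at 120 km
        from foragescape.simulate import PatchSpec, TrajectoryConfig
        cfg = TrajectoryConfig(seed=3, patches=[
            PatchSpec(center_km=(40.0, 0.0), radius_km=6.0, forage_h=4.0),
            PatchSpec(center_km=(120.0, 0.0), radius_km=6.0, forage_h=4.0)],
            n_excursions=1, rest_rate_per_h=0.0)
        traj, _ = simulate_trajectory(cfg)
        trip = segment_trips(classify_behaviour(traj))[0]
        path = interpolate_path(trip, 1.0)
        zones = delineate_ars_zones(path, 6.0)
        big = [z for z in zones if z.residence_h > 1.0]
        assert len(big) == 2
        assert big[0].entry_time < big[1].entry_time
        assert big[0].dist_colony_km < big[1].dist_colony_km


class TestTwoStage:
    def test_stage_radii_vectors(self):
        assert len(MESO_RADII_KM) == 50
        assert len(COARSE_RADII_KM) == 100
        assert MESO_RADII_KM[0] == 1.0 and MESO_RADII_KM[-1] == 50.0
        assert COARSE_RADII_KM[0] == pytest.approx(0.1)
        assert COARSE_RADII_KM[-1] == pytest.approx(10.0)

    def test_short_trip_resolves_no_meso_scale(self):
        trip = straight_trip(length_km=1.5, fix_km=0.25)
        res = two_stage_ars(trip)
        assert res.meso.scale_km is None
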