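import numpy as np
import pytest

from foragescape.grids import GridSpec, Raster
from foragescape.habitat import (auc_category, balanced_subsample,
                                 distance_to_colony, evaluate, fit_maxent,
                                 window_gradient)
from foragescape.simulate import simulate_presences, simulate_raster

GRID = GridSpec(xll=-26.0, yll=12.0, ncols=30, nrows=30, cell_deg=0.12)


def _noise(seed, name="X", grid=GRID):
    return simulate_raster(grid, "noise", {"sigma_cells": 2.0}, seed=seed,
                           name=name)


class TestWindowGradient:
    def test_constant_raster_gives_zeros(self):
        r = Raster("c", GRID, np.full((30, 30), 7.0))
        assert np.allclose(window_gradient(r).values, 0.0)

    def test_printed_formula_on_a_crafted_window(self):
        vals = np.full((3, 3), 10.0)
        vals[1, 1] = 5.0
        g = GridSpec(xll=0, yll=0, ncols=3, nrows=3, cell_deg=0.12)
        out = window_gradient(Raster("x", g, vals)).values
        # centre window: (10 - 5) * 100 / 10 = 50
        assert out[1, 1] == pytest.approx(50.0)

    def test_corner_uses_available_neighbours_only(self):
        vals = np.arange(9, dtype=float).reshape(3, 3) + 1.0
        g = GridSpec(xll=0, yll=0, ncols=3, nrows=3, cell_deg=0.12)
        out = window_gradient(Raster("x", g, vals)).values
        # top-left corner sees cells {1,2,4,5}: (5-1)*100/5 = 80
        assert out[0, 0] == pytest.approx(80.0)

    def test_zero_window_maximum_is_masked(self):
        vals = np.zeros((3, 3))
        g = GridSpec(xll=0, yll=0, ncols=3, nrows=3, cell_deg=0.12)
        out = window_gradient(Raster("x", g, vals)).values
        assert np.isnan(out).all()

    def test_equals_brute_force_recomputation(self, rng):
        g = GridSpec(xll=0, yll=0, ncols=20, nrows=20, cell_deg=0.12)
        for _ in range(5):
            vals = rng.uniform(0.5, 10.0, size=(20, 20))
            vals[rng.random((20, 20)) < 0.1] = np.nan
            out = window_gradient(Raster("x", g, vals)).values
            for i in range(20):
                for j in range(20):
                    win = vals[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
                    win = win[np.isfinite(win)]
                    if len(win) == 0 or win.max() == 0:
                        assert np.isnan(out[i, j])
                    else:
                        expect = (win.max() - win.min()) * 100.0 / win.max()
                        assert out[i, j] == expect


class TestDistanceToColony:
    def test_colony_cell_is_near_zero(self):
        colony = (float(GRID.lon_centers[10]), float(GRID.lat_centers[10]))
        d = distance_to_colony(GRID, colony).values
        assert d[10, 10] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_east_on_the_equator(self):
        g = GridSpec(xll=-0.06, yll=-0.06, ncols=20, nrows=1, cell_deg=0.12)
        d = distance_to_colony(g, (0.0, 0.0)).values
        lon = g.lon_centers
        k = int(np.argmin(np.abs(lon - 1.0)))
        expect = 6371.0088 * np.pi / 180 * lon[k]
        assert d[0, k] == pytest.approx(expect, rel=1e-9)

    def test_east_west_symmetry(self):
        g = GridSpec(xll=-1.2, yll=-0.12, ncols=20, nrows=2, cell_deg=0.12)
        d = distance_to_colony(g, (0.0, 0.0)).values
        assert np.allclose(d[:, ::-1], d, rtol=1e-9)


class TestBalancedSubsample:
    ZONES = {"a": list(range(5)), "b": list(range(100, 108)),
             "c": list(range(200, 212))}

    def test_min_rule(self):
        sel = balanced_subsample(self.ZONES, seed=1)
        assert len(sel) == 15
        assert sum(1 for s in sel if s < 100) == 5

    def test_same_seed_is_deterministic(self):
        assert balanced_subsample(self.ZONES, seed=9) == \
            balanced_subsample(self.ZONES, seed=9)

    def test_different_seeds_differ(self):
        base = balanced_subsample(self.ZONES, seed=0)
        assert any(balanced_subsample(self.ZONES, seed=s) != base
                   for s in range(1, 11))

    def test_empty_bird_is_an_error(self):
        with pytest.raises(ValueError):
            balanced_subsample({"a": [1], "b": []}, seed=0)


class TestFitMaxent:
    def test_uniform_presences_shrink_to_uniform_model(self):
        rasters = [_noise(1, "SST"), _noise(2, "CHL")]
        uniform = Raster("U", GRID, np.ones((30, 30)))
        for seed in range(5):
            pts, _ = simulate_presences(uniform, 150, seed=seed)
            m = fit_maxent(pts, rasters)
            logi = m.logistic(m.bg_X)
            assert np.abs(logi - 0.5).max() < 0.1
            assert np.abs(m.lambdas).max() < 1.0

    def test_single_driver_recovery(self):
        driver = _noise(1, "SST")
        rasters = [driver, _noise(2, "CHL"), _noise(3, "WSPD")]
        suit = Raster("S", GRID, np.exp(2.0 * driver.values))
        pts, _ = simulate_presences(suit, 250, seed=4)
        m = fit_maxent(pts, rasters)
        assert m.lambdas[0] > 0  # positive weight on the SST linear feature
        top = max(m.gain_increments, key=m.gain_increments.get)
        assert top == "SST"

    def test_logistic_output_is_in_unit_interval(self):
        driver = _noise(5, "SST")
        suit = Raster("S", GRID, np.exp(driver.values - driver.values.min()))
        pts, _ = simulate_presences(suit, 100, seed=0)
        m = fit_maxent(pts, [driver])
        logi = m.logistic(m.bg_X)
        assert ((logi > 0) & (logi < 1)).all()

    def test_regularized_moment_conditions_hold(self):
        driver = _noise(7, "SST")
        rasters = [driver, _noise(8, "CHL")]
        suit = Raster("S", GRID, np.exp(1.5 * driver.values))
        pts, _ = simulate_presences(suit, 200, seed=2)
        m = fit_maxent(pts, rasters)
        from foragescape.habitat import _design
        F_bg = _design(m.bg_X, m.scale_lo, m.scale_hi)
        eta = F_bg @ m.lambdas
        q = np.exp(eta - eta.max())
        q /= q.sum()
        pres_X = m.bg_X[np.searchsorted(m.bg_flat_index, m.presence_cells)]
        F_pres = _design(pres_X, m.scale_lo, m.scale_hi)
        gap = np.abs(F_pres.mean(axis=0) - q @ F_bg)
        # slack beyond beta reflects the 1e-6 gain tolerance of the
        # coordinate descent: residual gradient ~ sqrt(2 * var * tol)
        assert (gap <= m.beta + 2e-3).all()

    def test_nonfinite_predictor_at_presence_is_an_error(self):
        vals = _noise(1).values.copy()
        vals[15, 15] = np.nan
        bad = Raster("SST", GRID, vals)
        lon = GRID.lon_centers[15] + 0.01
        lat = GRID.lat_centers[15] - 0.01
        pts = np.vstack([np.column_stack([GRID.lon_centers[:12],
                                          GRID.lat_centers[:12]]),
                         [[lon, lat]]])
        with pytest.raises(ValueError, match="presence cell"):
            fit_maxent(pts, [bad])

    def test_too_few_presence_cells_is_an_error(self):
        pts = np.tile([[GRID.lon_centers[3], GRID.lat_centers[3]]], (30, 1))
        with pytest.raises(ValueError, match="10"):
            fit_maxent(pts, [_noise(1)])


class TestEvaluate:
    def _setup(self):
        driver = _noise(11, "SST")
        rasters = [driver, _noise(12, "CHL")]
        suit = Raster("S", GRID, np.exp(2.0 * driver.values))
        pts, _ = simulate_presences(suit, 200, seed=3)
        return pts, rasters

    def test_contributions_sum_to_100(self):
        pts, rasters = self._setup()
        ev = evaluate(pts, rasters, replicates=5, seed=1)
        assert sum(ev.percent_contribution.values()) == pytest.approx(100.0,
                                                                      abs=0.1)
        assert sum(ev.permutation_contribution.values()) == pytest.approx(
            100.0, abs=0.1)
        assert 0.0 <= ev.mean_auc <= 1.0

    def test_bitwise_reproducibility(self):
        pts, rasters = self._setup()
        ev1 = evaluate(pts, rasters, replicates=4, seed=42)
        ev2 = evaluate(pts, rasters, replicates=4, seed=42)
        assert np.array_equal(ev1.auc_per_replicate, ev2.auc_per_replicate)
        assert np.array_equal(ev1.mean_prediction.values,
                              ev2.mean_prediction.values, equal_nan=True)

    def test_jackknife_single_variable_gain_is_positive_for_a_driver(self):
        pts, rasters = self._setup()
        ev = evaluate(pts, rasters, replicates=3, seed=0)
        assert ev.jackknife["SST"]["alone"] > ev.jackknife["CHL"]["alone"]


@pytest.mark.parametrize("auc,label", [
    (0.95, "excellent"), (0.85, "good"), (0.75, "acceptable"),
    (0.65, "bad"), (0.55, "invalid"), (0.4, "invalid")])
def test_auc_category_bands(auc, label):
    assert auc_category(auc) == label
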