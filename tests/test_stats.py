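import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from magnetoguide import geometry
from magnetoguide.forces import HotSpot
from magnetoguide.kinetics import Track
from magnetoguide.stats import (
    estimate_velocity,
    occupancy,
    proportion_test,
    two_sample_t,
    uniform_null_fraction,
)
from magnetoguide.synthetic import synth_tracks


def _track(ts, xs, ys):
    return Track("t0", pd.DataFrame({"t_s": ts, "x_um": xs, "y_um": ys}))


class TestEstimateVelocity:
    def test_noiseless_constant_speed(self):
        tracks, _ = synth_tracks(1, speed_um_s=10.0, duration_s=5.0,
                                 noise_sigma_um=0.0, seed=1)
        fit = estimate_velocity(tracks)
        assert fit.slope_um_s == pytest.approx(10.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_static_track_zero_slope(self):
        fit = estimate_velocity(_track([0, 1, 2, 3], [5, 5, 5, 5], [2, 2, 2, 2]))
        assert fit.slope_um_s == pytest.approx(0.0)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            estimate_velocity(pd.DataFrame({"t_s": [0, 1, 1, 2], "x_um": [0, 1, 2, 3],
                                            "y_um": [0, 0, 0, 0]}))
        with pytest.raises(ValueError):
            estimate_velocity(pd.DataFrame({"t_s": [0.0], "x_um": [0.0], "y_um": [0.0]}))

    def test_position_scale_equivariance_and_time_shift_invariance(self):
        rng = np.random.default_rng(6)
        ts = np.arange(20.0)
        xs = 3.0 * ts + rng.normal(0, 0.3, 20)
        ys = rng.normal(0, 0.3, 20)
        base = estimate_velocity(pd.DataFrame({"t_s": ts, "x_um": xs, "y_um": ys}))
        scaled = estimate_velocity(pd.DataFrame({"t_s": ts, "x_um": 2 * xs, "y_um": 2 * ys}))
        shifted = estimate_velocity(pd.DataFrame({"t_s": ts + 100.0, "x_um": xs, "y_um": ys}))
        assert scaled.slope_um_s == pytest.approx(2 * base.slope_um_s, rel=1e-9)
        assert shifted.slope_um_s == pytest.approx(base.slope_um_s, rel=1e-9)

    def test_noisy_recovery_within_three_se(self):
        """OLS slope recovers the true speed within 3 SE in >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            tracks, _ = synth_tracks(1, speed_um_s=10.0, duration_s=59.0,
                                     frame_dt_s=1.0, noise_sigma_um=0.5, seed=seed)
            fit = estimate_velocity(tracks)
            if abs(fit.slope_um_s - 10.0) <= 3 * fit.stderr_um_s:
                hits += 1
        assert hits >= 95


class TestUniformNull:
    def test_permalloy_bar_array_null_fractions(self):
        p = geometry.build_bar_array()
        assert uniform_null_fraction(p, 10.0) == pytest.approx(0.175, abs=0.001)
        assert uniform_null_fraction(p, 0.0) == pytest.approx(0.1143, abs=0.0005)

    def test_full_coverage_null_is_one(self):
        p = geometry.PatternSpec(primitives=(geometry.Rect(0, 50, 0, 50),),
                                 unit_cell=(50.0, 50.0))
        assert uniform_null_fraction(p, 10.0) == pytest.approx(1.0)


class TestOccupancy:
    def test_empty_population(self):
        p = geometry.build_bar_array()
        rep = occupancy(pd.DataFrame({"x_um": [], "y_um": []}), p, [])
        assert rep.n_cells == 0 and rep.n_touching_pattern == 0
        assert rep.fraction_hot_spots_occupied is None

    def test_constructed_pole_occupation(self):
        """7 cells on 5 of 10 bar poles -> half the hot spots occupied."""
        p = geometry.build_bar_array(nx=5, ny=1)
        spots = []
        for i, r in enumerate(p.rectangles()):
            yc = (r.y1 + r.y2) / 2
            spots.append(HotSpot(r.x1, yc, 1.0, 2 * i))
            spots.append(HotSpot(r.x2, yc, 1.0, 2 * i + 1))
        assert len(spots) == 10
        occupied = spots[:5]
        xs = [h.x_um for h in occupied] + [occupied[0].x_um, occupied[1].x_um]
        ys = [h.y_um for h in occupied] + [occupied[0].y_um + 1, occupied[1].y_um - 1]
        rep = occupancy(pd.DataFrame({"x_um": xs, "y_um": ys}), p, spots)
        assert rep.n_cells == 7
        assert rep.fraction_hot_spots_occupied == pytest.approx(0.5)
        assert rep.n_touching_pattern == 7

    def test_touch_count_monotone_in_radius(self):
        rng = np.random.default_rng(8)
        p = geometry.build_bar_array()
        pos = pd.DataFrame({"x_um": rng.uniform(0, 350, 200),
                            "y_um": rng.uniform(0, 250, 200)})
        n0 = occupancy(pos, p, [], touch_radius_um=0.0).n_touching_pattern
        n10 = occupancy(pos, p, [], touch_radius_um=10.0).n_touching_pattern
        assert n10 >= n0

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(9)
        p = geometry.build_bar_array()
        pos = pd.DataFrame({"x_um": rng.uniform(0, 350, 50),
                            "y_um": rng.uniform(0, 250, 50)})
        shuffled = pos.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = occupancy(pos, p, [])
        b = occupancy(shuffled, p, [])
        assert a.to_dict() == b.to_dict()

    def test_cells_per_bar_counting(self):
        p = geometry.build_bar_array(nx=2, ny=1)
        bars = p.rectangles()
        # 3 cells on the first bar, 1 on the second
        pos = pd.DataFrame({
            "x_um": [(bars[0].x1 + bars[0].x2) / 2] * 3 + [(bars[1].x1 + bars[1].x2) / 2],
            "y_um": [(bars[0].y1 + bars[0].y2) / 2] * 3 + [(bars[1].y1 + bars[1].y2) / 2],
        })
        rep = occupancy(pos, p, [])
        assert rep.cells_per_bar_mean == pytest.approx(2.0)
        assert rep.cells_per_bar_sd == pytest.approx(np.std([3, 1], ddof=1))


class TestProportionTest:
    def test_null_value_gives_p_near_one(self):
        res = proportion_test(50, 100, 0.5, method="z-cc")
        assert abs(res["statistic"]) < 1e-12
        assert res["p_value"] == pytest.approx(1.0)

    def test_rejection_agrees_with_binomial_tail_oracle(self):
        # oracle: exact two-sided binomial tail enumeration via scipy
        k, n, p0 = 30, 100, 0.114
        oracle_p = sps.binomtest(k, n, p0).pvalue
        assert oracle_p < 0.05
        for method in ("exact", "z", "z-cc"):
            assert proportion_test(k, n, p0, method=method)["p_value"] < 0.05

    def test_normal_approximation_converges_to_exact(self):
        k, n, p0 = 196, 1000, 0.175
        p_exact = proportion_test(k, n, p0, method="exact")["p_value"]
        p_z = proportion_test(k, n, p0, method="z-cc")["p_value"]
        assert abs(p_exact - p_z) < 0.01

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_null_rejected(self, p0):
        with pytest.raises(ValueError):
            proportion_test(5, 10, p0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(11, 10, 0.5)


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_clear_shift_detected(self):
        res = two_sample_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res["p_value"] < 0.01
        assert res["t"] < 0

    def test_direction_agrees_with_permutation_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        pooled = np.concatenate([a, b])
        from itertools import combinations
        diffs = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            diffs.append(pooled[mask].mean() - pooled[~mask].mean())
        observed = a.mean() - b.mean()
        perm_p = np.mean(np.abs(diffs) >= abs(observed) - 1e-12)
        res = two_sample_t(a, b)
        # both see the shift in the same direction; t-test at least as extreme
        assert res["t"] < 0 and observed < 0
        assert perm_p == pytest.approx(2 / 20)

    def test_zero_variance_degenerate_flagged(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res["p_value"] == 1.0
        assert "degenerate" in res["method"]

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])
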