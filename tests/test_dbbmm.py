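import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icefox.dbbmm import (
    DbbmmParams,
    MotionVarianceProfile,
    bridge_variance,
    compute_ud,
    cells_to_polygon,
    estimate_static_sigma2,
    estimate_variance_profile,
    home_range,
    window_negloglik,
)
from icefox.grids import GridGeometry, UDGrid, cumulative_contour
from icefox.landmask import straight_coast_mask
from icefox.simulate import simulate_brownian_track
from conftest import make_traj
from oracles import bridge_negloglik_hand, dense_bridge_ud


class TestBridgeVariance:
    def test_endpoint_limits(self):
        assert bridge_variance(0.0, 3600, 1.0, 30.0, 40.0) == pytest.approx(900.0)
        assert bridge_variance(1.0, 3600, 1.0, 30.0, 40.0) == pytest.approx(1600.0)

    def test_midpoint_value(self):
        assert bridge_variance(0.5, 3600.0, 1.0, 0.0, 0.0) == pytest.approx(900.0)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            bridge_variance(1.5, 3600, 1.0, 0.0, 0.0)


class TestWindowNegloglik:
    def test_collinear_midpoint_minimizes_residual(self):
        on_line = make_traj([(0, 0, 0), (30, 500, 0), (60, 1000, 0)], error_radius=1e-9)
        offset = make_traj([(0, 0, 0), (30, 500, 100), (60, 1000, 0)], error_radius=1e-9)
        assert window_negloglik(on_line, 1.0) < window_negloglik(offset, 1.0)

    def test_matches_hand_evaluated_density(self):
        traj = make_traj([(0, 0, 0), (30, 500, 100), (60, 1000, 0)], error_radius=300.0)
        got = window_negloglik(traj, 2.0)
        expected = bridge_negloglik_hand(
            (500, 100), (0, 0), (1000, 0), 0.0, 1800.0, 3600.0, 2.0,
            sd1=150.0, sd2=150.0, sd_obs=150.0,
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_sigma2_errors(self):
        traj = make_traj([(0, 0, 0), (30, 500, 0), (60, 1000, 0)])
        with pytest.raises(ValueError):
            window_negloglik(traj, -1.0)

    def test_negloglik_minimized_near_true_sigma2(self, rng):
        traj = simulate_brownian_track(rng, n_fixes=151, sigma2m=50.0, error_sd_m=20.0)
        grid = np.logspace(-1, 4, 60)
        nlls = [window_negloglik(traj, s2) for s2 in grid]
        s2_hat = grid[int(np.argmin(nlls))]
        assert 0.5 * 50 <= s2_hat <= 2 * 50


class TestVarianceProfile:
    def test_constant_brownian_recovery(self, rng):
        traj = simulate_brownian_track(rng, n_fixes=200, sigma2m=100.0)
        prof = estimate_variance_profile(traj)
        assert len(prof.sigma2m) == 199
        assert abs(prof.sigma2m.mean() - 100.0) / 100.0 < 0.3

    def test_step_change_splits_halves(self, rng):
        lo, hi = 0.05, 5.0
        means_lo, means_hi = [], []
        for _ in range(5):
            traj = simulate_brownian_track(
                rng, n_fixes=200, sigma2m=lo, sigma2m_second=hi, error_sd_m=10.0
            )
            prof = estimate_variance_profile(traj)
            mid = (len(traj) - 1) // 2
            means_lo.append(prof.sigma2m[:mid].mean())
            means_hi.append(prof.sigma2m[mid:].mean())
        m_lo, m_hi = np.mean(means_lo), np.mean(means_hi)
        # each half's estimate is closer (in log space) to its own truth
        assert abs(np.log(m_lo / lo)) < abs(np.log(m_lo / hi))
        assert abs(np.log(m_hi / hi)) < abs(np.log(m_hi / lo))

    def test_too_few_locations_errors(self):
        traj = make_traj([(i * 30, i * 100, 0) for i in range(5)])
        with pytest.raises(ValueError, match="at least 7"):
            estimate_variance_profile(traj)

    def test_short_track_falls_back_to_static(self):
        traj = make_traj([(i * 30, i * 100, 0) for i in range(8)])
        with pytest.warns(UserWarning, match="static"):
            prof = estimate_variance_profile(traj, DbbmmParams(window_size=9))
        assert prof.static
        assert len(np.unique(prof.sigma2m)) == 1

    def test_profile_length_and_nonnegativity(self, rng):
        traj = simulate_brownian_track(rng, n_fixes=40)
        prof = estimate_variance_profile(traj)
        assert len(prof.sigma2m) == 39
        assert np.all(prof.sigma2m >= 0)
        assert np.all(prof.n_estimates >= 1)


class TestComputeUD:
    def test_mass_sums_to_one(self, rng):
        traj = simulate_brownian_track(rng, n_fixes=30)
        prof = estimate_variance_profile(traj)
        ud = compute_ud(traj, prof)
        assert abs(ud.total_mass - 1.0) <= 1e-9

    def test_degenerate_bridge_concentrates_on_segment(self):
        traj = make_traj([(0, 0, 0), (60, 5000, 0)], error_radius=1e-6)
        prof = MotionVarianceProfile(np.array([1e-8]), np.array([1]))
        ud = compute_ud(traj, prof, DbbmmParams(cell_size=250.0))
        ys = ud.geometry.y_centers
        on_axis = np.abs(ys) < 250
        assert ud.values[on_axis, :].sum() > 0.99

    def test_symmetric_bridge_ud_is_symmetric(self):
        traj = make_traj([(0, -1000, 0), (60, 1000, 0)], error_radius=500.0)
        prof = MotionVarianceProfile(np.array([1.0]), np.array([1]))
        ud = compute_ud(traj, prof, DbbmmParams(cell_size=100.0))
        np.testing.assert_allclose(ud.values, ud.values[:, ::-1], atol=1e-9)

    def test_empty_trajectory_errors(self):
        traj = make_traj([(0, 0, 0)]).iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            compute_ud(traj, MotionVarianceProfile(np.empty(0), np.empty(0, int)))

    def test_static_limit_matches_dense_oracle(self, rng):
        """With one sigma2m over the whole track, the fast local-window UD
        equals an independent dense per-cell Brownian-bridge evaluation."""
        traj = simulate_brownian_track(rng, n_fixes=20)
        prof = estimate_static_sigma2(traj)
        ud = compute_ud(traj, prof, DbbmmParams(cell_size=250.0))
        oracle = dense_bridge_ud(traj, prof.sigma2m[0], ud.geometry)
        assert np.abs(oracle - ud.values).max() <= 1e-6


class TestContours:
    def test_enumerable_cases(self):
        ud = UDGrid(GridGeometry(0, 0, 1, 1, 3), np.array([[0.5, 0.3, 0.2]]))
        assert cumulative_contour(ud, 0.75).tolist() == [[True, True, False]]
        assert cumulative_contour(ud, 0.5).tolist() == [[True, False, False]]

    def test_tie_break_is_lexicographic(self):
        ud = UDGrid(GridGeometry(0, 0, 1, 2, 2), np.full((2, 2), 0.25))
        assert cumulative_contour(ud, 0.4).tolist() == [[True, True], [False, False]]

    def test_unnormalized_errors(self):
        ud = UDGrid(GridGeometry(0, 0, 1, 1, 2), np.array([[0.5, 0.3]]))
        with pytest.raises(ValueError, match="normalized"):
            cumulative_contour(ud, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        p1=st.floats(0.05, 0.9),
        delta=st.floats(0.01, 0.09),
    )
    def test_nesting_on_random_grids(self, seed, p1, delta):
        r = np.random.default_rng(seed)
        vals = r.random((8, 9))
        ud = UDGrid(GridGeometry(0, 0, 1, 8, 9), vals / vals.sum())
        inner = cumulative_contour(ud, p1)
        outer = cumulative_contour(ud, p1 + delta)
        assert not np.any(inner & ~outer)
        assert ud.values[inner].sum() >= p1


class TestHomeRange:
    def test_reduces_to_contour_when_all_on_land(self, rng):
        mask = straight_coast_mask(60_000, 15_000)
        traj = simulate_brownian_track(rng, n_fixes=30)
        traj["y"] += 8000.0  # put the whole track on land
        contour, poly, ud = home_range(traj, mask)
        prof = estimate_variance_profile(traj)
        direct = cumulative_contour(compute_ud(traj, prof, grid=ud.geometry), 0.5)
        assert np.array_equal(contour, direct)
        assert ud.values[contour].sum() >= 0.5
        assert poly.area > 0

    def test_sea_excursion_fixes_excluded(self, rng):
        mask = straight_coast_mask(60_000, 15_000)
        pts = [(i * 40, 2000 + 50 * i, 3000) for i in range(10)]
        pts.insert(5, (5 * 40 - 20, 2100, -4000))  # one fix at sea
        traj = make_traj(pts)
        contour, poly, ud = home_range(traj, mask)
        sea_rows = ud.geometry.y_centers < -1000
        assert ud.values[sea_rows, :].sum() < 0.01

    def test_too_few_on_land_fixes_name_the_animal(self):
        mask = straight_coast_mask(60_000, 15_000)
        traj = make_traj([(i * 30, i * 100, -5000) for i in range(10)], animal_id="FX7")
        with pytest.raises(ValueError, match="FX7"):
            home_range(traj, mask)


def test_cells_to_polygon_dissolves_adjacent_cells():
    geom = GridGeometry(0, 0, 10, 3, 3)
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 0] = mask[0, 1] = True
    poly = cells_to_polygon(mask, geom)
    assert poly.area == pytest.approx(200.0)
    assert poly.geom_type == "Polygon"
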