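"""Movement simulator: OU kernel, activity schedule, bridges, home ranges."""

import numpy as np
import pytest

from camabund.movement import (
    DEFAULT_REST_HOURS,
    MovementScenario,
    brownian_bridge_refine,
    draw_group_sizes,
    draw_home_range_centers,
    refine_trajectory,
    simulate_ou_trajectory,
    stationary_hra,
)


class TestStationaryHRA:
    @pytest.mark.parametrize(
        "sigma,expected",
        [(150, 0.65), (300, 2.61), (600, 10.38), (1200, 41.58)],
    )
    def test_emergent_home_range_areas(self, sigma, expected):
        """The 99% stationary contour reproduces the emergent HRAs."""
        assert stationary_hra(sigma) == pytest.approx(expected, rel=0.01)

    def test_scales_with_sigma_squared(self):
        sigmas = np.array([100.0, 200.0, 400.0, 800.0])
        areas = np.array([stationary_hra(s) for s in sigmas])
        assert (np.diff(areas) > 0).all()
        assert areas[1:] / areas[:-1] == pytest.approx([4.0, 4.0, 4.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stationary_hra(-1.0)
        with pytest.raises(ValueError):
            stationary_hra(150.0, quantile=1.5)


class TestHomeRangeCenters:
    def test_closure_centers_are_grid_centroids(self, rng, grid):
        scn = MovementScenario(N=480, sigma=150, rho=0.7, closure="closed")
        centers = draw_home_range_centers(scn, grid.centroids(), rng)
        assert centers.shape == (40, 2)
        cents = grid.centroids()
        for c in centers:
            assert np.isclose(cents, c).all(axis=1).any()

    def test_open_centers_uniform_support_and_mean(self, rng, grid):
        scn = MovementScenario(N=10_000, G=10_000, sigma=150, rho=0.7, closure="open")
        centers = draw_home_range_centers(scn, grid.centroids(), rng)
        assert centers.min() >= 0.0 and centers.max() <= 10_800.0
        # uniform mean 5400 with SE = 10800/sqrt(12)/100 ~ 31.2 m
        assert abs(centers[:, 0].mean() - 5400.0) < 3 * 31.2

    def test_single_open_center_in_extent(self, rng, grid):
        scn = MovementScenario(N=1, G=1, sigma=150, rho=0.7, closure="open")
        c = draw_home_range_centers(scn, grid.centroids(), rng)
        assert c.shape == (1, 2)
        assert (c >= 0).all() and (c <= 10_800).all()


class TestGroupSizes:
    def test_all_singletons_when_N_equals_G(self, rng):
        assert (draw_group_sizes(40, 40, rng=rng) == 1).all()

    @pytest.mark.parametrize("N", [480, 240, 120, 60])
    def test_sizes_sum_to_population(self, rng, N):
        sizes = draw_group_sizes(N, 40, rng=rng)
        assert len(sizes) == 40
        assert sizes.sum() == N
        assert (sizes >= 1).all() and (sizes <= 30).all()

    def test_seeded_determinism(self):
        a = draw_group_sizes(120, 40, rng=np.random.default_rng(7))
        b = draw_group_sizes(120, 40, rng=np.random.default_rng(7))
        assert (a == b).all()

    def test_infeasible_allocation_raises(self, rng):
        with pytest.raises(ValueError):
            draw_group_sizes(39, 40, rng=rng)
        with pytest.raises(ValueError):
            # 40 groups of at most 30 cannot reach 2000
            draw_group_sizes(2000, 40, rng=rng)


class TestOUTrajectory:
    def test_rest_hour_identity(self, rng):
        pos = simulate_ou_trajectory((0.0, 0.0), 300.0, 0.7, 240, rng=rng)
        for k in range(1, 240):
            if (k + 1) % 24 in DEFAULT_REST_HOURS:
                assert (pos[k] == pos[k - 1]).all()

    def test_stationary_variance_and_autocorrelation(self, rng):
        sigma, rho, T = 300.0, 0.95, 120_000
        pos = simulate_ou_trajectory(
            (0.0, 0.0), sigma, rho, T, rest_hours=frozenset(), rng=rng
        )
        for coord in range(2):
            x = pos[:, coord]
            assert np.var(x) == pytest.approx(sigma**2, rel=0.05)
            r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert r1 == pytest.approx(rho, abs=0.02)

    def test_conditional_mean_is_linear_shrinkage(self, rng):
        """Regressing u[t+1] on u[t] recovers slope rho and centre s."""
        s, rho = np.array([500.0, -200.0]), 0.7
        pos = simulate_ou_trajectory(s, 150.0, rho, 50_000, rest_hours=frozenset(), rng=rng)
        for coord in range(2):
            slope, intercept = np.polyfit(pos[:-1, coord], pos[1:, coord], 1)
            assert slope == pytest.approx(rho, abs=0.02)
            assert intercept == pytest.approx((1 - rho) * s[coord], rel=0.1)

    def test_seeded_bit_reproducibility(self):
        a = simulate_ou_trajectory((0, 0), 150, 0.7, 600, rng=np.random.default_rng(3))
        b = simulate_ou_trajectory((0, 0), 150, 0.7, 600, rng=np.random.default_rng(3))
        assert (a == b).all()


class TestBrownianBridge:
    def test_zero_scale_is_straight_segment(self, rng):
        p0, p1 = np.array([0.0, 0.0]), np.array([60.0, 30.0])
        interior = brownian_bridge_refine(p0, p1, 6, 0.0, rng)
        f = np.arange(1, 6)[:, None] / 6
        assert interior == pytest.approx((1 - f) * p0 + f * p1)

    def test_rest_degenerate_bridge(self, rng):
        p = np.array([10.0, 10.0])
        interior = brownian_bridge_refine(p, p, 6, 0.0, rng)
        assert (interior == p).all()

    def test_single_substep_returns_empty_interior(self, rng):
        out = brownian_bridge_refine((0, 0), (1, 1), 1, 50.0, rng)
        assert out.shape == (0, 2)

    def test_midpoint_variance(self, rng):
        """Interior variance follows scale^2 * f * (1 - f)."""
        scale, B, n = 40.0, 6, 20_000
        mids = np.array(
            [brownian_bridge_refine((0, 0), (0, 0), B, scale, rng)[2] for _ in range(n)]
        )
        assert mids.var(axis=0) == pytest.approx(0.25 * scale**2, rel=0.05)

    def test_refine_keeps_hourly_positions_and_rest_repeats(self, rng):
        hourly = np.array([[0.0, 0.0], [60.0, 0.0], [60.0, 0.0], [0.0, 30.0]])
        fine = refine_trajectory(hourly, 6, 25.0, rng)
        assert fine.shape == (19, 2)
        assert (fine[::6] == hourly).all()
        # zero-displacement (rest) transition: no bridge noise
        assert (fine[7:12] == hourly[1]).all()


class TestScenario:
    def test_group_count_capped_at_population(self):
        scn = MovementScenario(N=30, sigma=1200, rho=0.7, closure="open")
        assert scn.G == 30

    def test_decline_preserves_scenario(self):
        scn = MovementScenario(N=480, sigma=150, rho=0.7)
        declined = scn.with_population(432)
        assert declined.N == 432 and declined.sigma == scn.sigma

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MovementScenario(N=10, sigma=150, rho=1.2)
        with pytest.raises(ValueError):
            MovementScenario(N=10, sigma=-5, rho=0.5)
        with pytest.raises(ValueError):
            MovementScenario(N=0, sigma=150, rho=0.5)


class TestInterfaces:
    def test_trajectory_csv_frame(self, rng, grid):
        from camabund.movement import simulate_population, trajectories_to_frame

        scn = MovementScenario(N=6, G=3, sigma=150, rho=0.7, n_days=1)
        groups = simulate_population(scn, grid.centroids(), rng)
        df = trajectories_to_frame(groups, scn.substeps)
        assert list(df.columns) == ["group_id", "step_index", "substep_index", "x_m", "y_m"]
        g0 = df[df.group_id == 0]
        hourly = g0[g0.substep_index == 0][["x_m", "y_m"]].to_numpy()
        assert hourly == pytest.approx(groups[0].hourly_positions)

    def test_scenario_from_yaml(self, tmp_path):
        p = tmp_path / "scn.yaml"
        p.write_text("N: 120\nsigma: 300\nrho: 0.95\nclosure: open\nrest_hours: [0, 1, 2]\n")
        scn = MovementScenario.from_yaml(p)
        assert scn.N == 120 and scn.rho == 0.95
        assert scn.rest_hours == frozenset({0, 1, 2})
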