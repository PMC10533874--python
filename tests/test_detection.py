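"""Camera placement, viewshed geometry, crossing counts, thinning."""

import numpy as np
import pytest

from camabund.detection import (
    Camera,
    Grid,
    SurveyData,
    count_viewshed_crossings,
    perfect_detection_field,
    place_cameras,
    sample_camera_cells,
    segment_crosses_viewshed,
    simulate_matern_detection_field,
    thin_and_aggregate,
)
from camabund.movement import GroupTrajectory


class TestCameraSampling:
    def test_default_design_places_36_cameras(self, grid, rng):
        cells = sample_camera_cells(grid, 0.25, rng)
        assert len(cells) == 36
        assert len(set(cells.tolist())) == 36

    def test_one_camera_per_2x2_block(self, grid, rng):
        cells = sample_camera_cells(grid, 0.25, rng)
        rows, cols = np.divmod(cells, grid.n_side)
        blocks = {(r // 2, c // 2) for r, c in zip(rows, cols)}
        assert len(blocks) == 36  # every block hit exactly once

    def test_full_fraction_selects_all_cells(self, grid, rng):
        assert (sample_camera_cells(grid, 1.0, rng) == np.arange(144)).all()

    def test_invalid_fraction(self, grid, rng):
        with pytest.raises(ValueError):
            sample_camera_cells(grid, 0.0, rng)


class TestViewshedGeometry:
    def test_segment_inside_sector(self, north_camera):
        assert segment_crosses_viewshed((0, 10), (0, 12), north_camera)

    def test_segment_east_outside_wedge(self, north_camera):
        assert not segment_crosses_viewshed((10, 0), (12, 0), north_camera)

    def test_transversal_chord_through_wedge(self, north_camera):
        assert segment_crosses_viewshed((-20, 8), (20, 8), north_camera)

    def test_far_segment_misses(self, north_camera):
        assert not segment_crosses_viewshed((100, 100), (120, 100), north_camera)

    def test_agrees_with_dense_sampling_oracle(self, north_camera):
        """Exact test vs dense point sub-sampling, away from the boundary."""
        rng = np.random.default_rng(5)
        cam = north_camera
        half = cam.view_angle / 2.0
        checked = 0
        for _ in range(400):
            p0 = rng.uniform(-30, 30, 2)
            p1 = rng.uniform(-30, 30, 2)
            t = np.linspace(0, 1, 2001)[:, None]
            pts = p0 + t * (p1 - p0)
            r = np.hypot(pts[:, 0], pts[:, 1])
            ang = np.degrees(np.arctan2(pts[:, 0], pts[:, 1]))
            inside = (r <= cam.radius) & (np.abs(ang) <= half)
            margin = 1e-3
            clearly_in = ((r <= cam.radius - margin) & (np.abs(ang) <= half - margin)).any()
            clearly_out = not ((r <= cam.radius + margin) & (np.abs(ang) <= half + margin)).any()
            if clearly_in:
                assert segment_crosses_viewshed(p0, p1, cam)
                checked += 1
            elif clearly_out:
                assert not segment_crosses_viewshed(p0, p1, cam)
                checked += 1
        assert checked > 200  # the oracle decided most cases

    def test_sector_area_fraction_of_disc(self, north_camera):
        """Point-in-sector frequency over the bounding disc ~ view_angle/360."""
        rng = np.random.default_rng(11)
        n = 20_000
        r = north_camera.radius * np.sqrt(rng.uniform(size=n))
        a = rng.uniform(0, 2 * np.pi, size=n)
        pts = np.column_stack([r * np.sin(a), r * np.cos(a)])
        hits = np.array([segment_crosses_viewshed(p, p, north_camera) for p in pts])
        assert hits.mean() == pytest.approx(42 / 360, abs=0.01)


def _survey_layout(hourly, size=5, substeps=2, n_days=2, steps_per_day=4):
    """Wrap a handmade hourly path into a GroupTrajectory with straight bridges."""
    from camabund.movement import refine_trajectory

    fine = refine_trajectory(np.asarray(hourly, float), substeps, 0.0, np.random.default_rng(0))
    return GroupTrajectory(
        group_id=0,
        size=size,
        center=np.asarray(hourly[0], float),
        hourly_positions=np.asarray(hourly, float),
        fine_positions=fine,
    )


class TestCrossingCounts:
    def test_no_crossings_gives_all_zero(self, north_camera):
        far = [[1000.0, 1000.0]] * 8
        traj = _survey_layout(far)
        n = count_viewshed_crossings([traj], [north_camera], 2, 4, 2)
        assert n.shape == (1, 2, 4)
        assert n.sum() == 0

    def test_single_crossing_counts_full_group_once(self, north_camera):
        # crossing during hour 1 only (transition from position 1 to 2)
        hourly = [[500, 500], [-20, 8], [20, 8], [500, 500], [500, 500],
                  [500, 500], [500, 500], [500, 500]]
        traj = _survey_layout(hourly, size=5)
        n = count_viewshed_crossings([traj], [north_camera], 2, 4, 2)
        assert n[0, 0, 1] == 5
        assert n.sum() == 5

    def test_resting_group_inside_viewshed_counts_each_hour(self, north_camera):
        inside = [0.0, 10.0]
        hourly = [inside] * 8  # stationary inside the sector the whole survey
        traj = _survey_layout(hourly, size=3)
        n = count_viewshed_crossings([traj], [north_camera], 2, 4, 2)
        assert (n == 3).all()  # once per hour, every hour, full group size


class TestThinning:
    def test_perfect_detection_keeps_counts(self, rng):
        n_ijh = rng.poisson(1.0, size=(4, 3, 24))
        cams = place_cameras(Grid(), np.arange(4))
        sd = thin_and_aggregate(n_ijh, perfect_detection_field(4), cams, rng)
        assert (sd.hourly_counts == n_ijh).all()
        assert (sd.counts == n_ijh.sum(axis=2)).all()

    def test_thinning_never_increases_and_conserves_totals(self, rng):
        from camabund.detection import DetectionField

        n_ijh = rng.poisson(2.0, size=(5, 4, 24))
        fld = DetectionField(
            prob=np.full(5, 2 / 3), covariate=np.zeros(5), regime="spatial"
        )
        cams = place_cameras(Grid(), np.arange(5))
        sd = thin_and_aggregate(n_ijh, fld, cams, rng)
        assert (sd.hourly_counts <= n_ijh).all()
        assert (sd.counts == sd.hourly_counts.sum(axis=2)).all()

    def test_binomial_thinning_mean(self, rng):
        from camabund.detection import DetectionField

        n_ijh = np.full((1, 10_000, 1), 6)
        fld = DetectionField(prob=np.array([2 / 3]), covariate=np.zeros(1), regime="spatial")
        cams = place_cameras(Grid(), np.arange(1))
        sd = thin_and_aggregate(n_ijh, fld, cams, rng)
        se = np.sqrt(6 * (2 / 3) * (1 / 3) / 10_000)
        assert sd.hourly_counts.mean() == pytest.approx(4.0, abs=4 * se)

    def test_binary_reduction(self, rng):
        counts = np.array([[0, 2], [1, 0]])
        cams = place_cameras(Grid(), np.arange(2))
        sd = SurveyData(counts=counts, cameras=cams, detection=perfect_detection_field(2))
        assert (sd.binary == np.array([[0, 1], [1, 0]])).all()


class TestMaternField:
    def test_zero_variance_gives_constant_two_thirds(self, grid, rng):
        cams = place_cameras(grid, sample_camera_cells(grid, 0.25, rng))
        fld = simulate_matern_detection_field(cams, variance=0.0, rng=rng)
        assert fld.prob == pytest.approx(np.full(36, 2 / 3))

    def test_mean_probability_near_two_thirds(self, grid, rng):
        cams = place_cameras(grid, sample_camera_cells(grid, 0.25, rng))
        means = [
            simulate_matern_detection_field(cams, rng=rng).prob.mean()
            for _ in range(300)
        ]
        assert np.mean(means) == pytest.approx(2 / 3, abs=0.03)

    def test_spatial_correlation_decays_with_distance(self, grid, rng):
        cams = place_cameras(grid, sample_camera_cells(grid, 0.25, np.random.default_rng(2)))
        X = np.array([[c.x, c.y] for c in cams])
        fields = np.array(
            [simulate_matern_detection_field(cams, rng=rng).covariate for _ in range(400)]
        )
        C = np.corrcoef(fields.T)
        D = np.hypot(*(X[:, None, :] - X[None, :, :]).transpose(2, 0, 1))
        iu = np.triu_indices(36, 1)
        near = C[iu][D[iu] < 2000]
        far = C[iu][D[iu] > 8000]
        assert near.mean() > far.mean() + 0.2


class TestSurveyIO:
    def test_csv_roundtrip(self, grid, rng, tmp_path):
        cams = place_cameras(grid, sample_camera_cells(grid, 0.25, rng))
        counts = rng.poisson(0.5, size=(36, 25))
        sd = SurveyData(counts=counts, cameras=cams, detection=perfect_detection_field(36))
        path = tmp_path / "survey.csv"
        sd.to_csv(path)
        back = SurveyData.from_csv(path)
        assert (back.counts == counts).all()
        assert [c.cell_id for c in back.cameras] == [c.cell_id for c in cams]
        assert back.detection.regime == "perfect"
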