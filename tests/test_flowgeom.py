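"""Centerline geometry, flow projection, segmentation and statistics."""

import numpy as np
import pandas as pd
import pytest

from cardioflow import DegenerateGeometryError, Track, TrackSet, VectorField4D
from cardioflow import flowgeom as fg

QUARTIC = np.array([
    [3.0, 0.5, -0.2, 0.01, 0.002],
    [50.0, 8.0, 1.0, -0.3, 0.02],
    [40.0, -5.0, 2.0, 0.1, -0.01],
])


def quartic_points(theta):
    return (theta[:, None] ** np.arange(5)[None, :]) @ QUARTIC.T


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=3)
    angle = np.linalg.norm(a)
    k = a / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-30, 30, 3)
    return R, t


class TestPrincipalPlane:
    def test_planar_cloud_normal_is_z(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([np.zeros(40), rng.uniform(-20, 20, 40),
                               rng.uniform(-20, 20, 40)])
        _, _, normal = fg.fit_principal_plane(pts)
        assert abs(abs(normal[0]) - 1.0) < 1e-12

    def test_rotated_plane_recovered(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([np.zeros(60), rng.uniform(-20, 20, 60),
                               rng.uniform(-20, 20, 60)])
        R, t = random_rigid(2)
        _, _, normal = fg.fit_principal_plane(pts @ R.T + t)
        true_normal = R @ np.array([1.0, 0, 0])
        angle = np.arccos(np.clip(abs(normal @ true_normal), 0, 1))
        assert angle < 1e-6

    def test_two_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fg.fit_principal_plane(np.array([[0, 0, 0], [1, 1, 1.0]]))

    def test_collinear_degenerate(self):
        line = np.outer(np.linspace(0, 1, 20), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fg.fit_principal_plane(line)


class TestTheta:
    BASIS = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])

    def test_first_basis_vector_zero_angle(self):
        th = fg.compute_theta(np.array([[0.0, 5.0, 0.0]]), np.zeros(3), self.BASIS)
        assert th[0] == pytest.approx(0.0)

    def test_second_basis_vector_quarter_turn(self):
        th = fg.compute_theta(np.array([[0.0, 0.0, 5.0]]), np.zeros(3), self.BASIS)
        assert th[0] == pytest.approx(np.pi / 2)

    def test_antipodal_points_differ_by_pi(self):
        th = fg.compute_theta(
            np.array([[0.0, 5.0, 1.0], [0.0, -5.0, -1.0]]), np.zeros(3), self.BASIS
        )
        assert abs(th[0] - th[1]) == pytest.approx(np.pi)

    def test_cloud_spanning_seam_stays_contiguous(self):
        ang = np.concatenate([np.linspace(-0.5, 0.5, 20) + np.pi,
                              np.linspace(-0.5, 0.5, 20) - np.pi]) % (2 * np.pi)
        pts = np.column_stack([np.zeros(40), 5 * np.cos(ang), 5 * np.sin(ang)])
        th = fg.compute_theta(pts, np.zeros(3), self.BASIS)
        assert th.max() - th.min() < 1.2      # ~1.0 rad true span, no 2 pi split

    def test_center_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            fg.compute_theta(np.zeros((1, 3)), np.zeros(3), self.BASIS)


class TestCenterlineFit:
    def test_quartic_coefficients_recovered_exactly(self):
        theta = np.linspace(0.2, 2.2, 60)
        c = fg.fit_centerline(quartic_points(theta), theta=theta)
        rel = np.abs(c.coefficients - QUARTIC) / np.abs(QUARTIC)
        assert rel.max() < 1e-6

    def test_fitted_curve_near_points_without_theta_override(self):
        theta = np.linspace(0.2, 2.2, 80)
        pts = quartic_points(theta)
        c = fg.fit_centerline(pts)
        d = np.linalg.norm(pts[:, None, :] - c.samples_um[None], axis=2).min(axis=1)
        assert d.max() < 2.0

    def test_noise_degrades_gracefully(self):
        theta = np.linspace(0.2, 2.2, 150)
        pts = quartic_points(theta)
        means = {}
        for sigma in (0.5, 1.0):
            errs = []
            for seed in range(5):
                noisy = pts + np.random.default_rng(seed).normal(0, sigma, pts.shape)
                c = fg.fit_centerline(noisy)
                errs.append(np.linalg.norm(c.residuals_um))
            means[sigma] = np.mean(errs)
            # residual tracks the injected noise (coordinate noise plus its
            # angle-noise image, so between 1x and ~3x sigma per coordinate)
            assert sigma * np.sqrt(3) * 0.8 < means[sigma] < sigma * np.sqrt(3) * 3
        # error grows sublinearly: doubling sigma less than triples residual
        assert means[1.0] < 3 * means[0.5]

    def test_too_few_points_or_small_span_rejected(self):
        # short arc about an explicit flow center: theta span too small
        ang = np.linspace(0.0, 0.1, 40)
        arc = np.column_stack(
            [np.zeros(40), 40 * np.sin(ang), 40 * np.cos(ang)]
        )
        with pytest.raises(DegenerateGeometryError):
            fg.fit_centerline(arc, center_um=np.zeros(3))
        with pytest.raises(DegenerateGeometryError):
            fg.fit_centerline(quartic_points(np.linspace(0.2, 2.2, 8)))

    def test_av_point_orients_curve(self):
        theta = np.linspace(0.2, 2.2, 60)
        pts = quartic_points(theta)
        end_min = quartic_points(np.array([0.2]))[0]
        end_max = quartic_points(np.array([2.2]))[0]
        c1 = fg.fit_centerline(pts, av_point_um=end_min)
        c2 = fg.fit_centerline(pts, av_point_um=end_max)
        assert np.linalg.norm(c1.samples_um[0] - end_min) < 1.0
        assert np.linalg.norm(c2.samples_um[0] - end_max) < 1.0
        # arc length starts at the AV end in both orientations
        assert c1.arc_length_um[0] == 0.0 and c2.arc_length_um[0] == 0.0


class TestProjection:
    def _line_track(self, velocity, n=10):
        pos = np.outer(np.arange(n), [0.0, 1.0, 0.0]) + [3.0, 45.0, 40.0]
        vel = np.tile(np.asarray(velocity, float), (n, 1))
        vel[-1] = np.nan
        return TrackSet([Track(0, np.arange(n), pos, vel)])

    def _centerline(self):
        theta = np.linspace(0.2, 2.2, 80)
        return fg.fit_centerline(quartic_points(theta))

    def test_parallel_velocity_projects_to_magnitude(self):
        c = self._centerline()
        tracks = TrackSet([])
        pos = c.samples_um[50:53]
        vel = 700.0 * c.tangents[50:53]
        tracks = TrackSet([Track(0, np.arange(3), pos, vel)])
        series = fg.project_flow_velocity(tracks, c)
        assert np.allclose(series.dropna(), 700.0, atol=1e-6)

    def test_perpendicular_velocity_projects_to_zero(self):
        c = self._centerline()
        e1, _ = fg._transported_frames(c)
        pos = c.samples_um[40:42]
        vel = 500.0 * e1[40:42]
        series = fg.project_flow_velocity(
            TrackSet([Track(0, np.arange(2), pos, vel)]), c
        )
        assert np.allclose(series.dropna(), 0.0, atol=1e-6)

    def test_projection_bounded_by_speed(self):
        rng = np.random.default_rng(3)
        c = self._centerline()
        pos = c.samples_um[rng.integers(0, 200, 30)] + rng.normal(0, 5, (30, 3))
        vel = rng.normal(0, 800, (30, 3))
        ts = TrackSet([Track(0, np.arange(30), pos, vel)])
        series = fg.project_flow_velocity(ts, c)
        speeds = np.linalg.norm(vel, axis=1)
        assert np.all(np.abs(series.to_numpy()[:30]) <= speeds + 1e-9)

    def test_empty_frames_flagged_missing(self):
        c = self._centerline()
        pos = c.samples_um[[10, 30]]
        vel = np.tile([0.0, 100.0, 0.0], (2, 1))
        ts = TrackSet([Track(0, np.array([0, 4]), pos, vel)])
        series = fg.project_flow_velocity(ts, c)
        assert np.isnan(series.loc[2])
        assert np.isfinite(series.loc[0])


class TestReversal:
    def test_all_positive_no_reversal(self):
        assert fg.detect_reversal(np.full(40, 500.0)) == []

    def test_single_lobe_interval(self):
        v = np.full(60, 200.0)
        v[30:36] = -1500.0
        assert fg.detect_reversal(v, 1000.0) == [(30, 35)]

    def test_shallow_lobe_below_threshold_ignored(self):
        v = np.full(60, 200.0)
        v[30:36] = -800.0
        assert fg.detect_reversal(v, 1000.0) == []

    def test_lobe_at_series_end_closed(self):
        v = np.full(10, -2000.0)
        assert fg.detect_reversal(v, 1000.0) == [(0, 9)]


class TestTubeCoordinates:
    def _centerline(self):
        # ventricle-scale arc (curvature radius 40 um) so that tube offsets
        # of a few microns stay far below the curvature radius
        ang = np.linspace(0.0, 2.5, 120)
        pts = np.column_stack(
            [np.full(120, 30.0), 60 + 40 * np.sin(ang), 60 + 40 * np.cos(ang)]
        )
        return fg.fit_centerline(pts, center_um=np.array([30.0, 60.0, 60.0]))

    def test_sample_point_maps_to_zero_offsets(self):
        c = self._centerline()
        coords = fg.to_centerline_coords(c.samples_um[77], c)
        assert coords[0, 0] == pytest.approx(c.arc_length_um[77], abs=1e-9)
        assert np.allclose(coords[0, 1:], 0.0, atol=1e-9)

    def test_normal_displacement_read_back(self):
        c = self._centerline()
        e1, e2 = fg._transported_frames(c)
        p = c.samples_um[60] + 7.0 * e1[60]
        coords = fg.to_centerline_coords(p, c)
        assert np.hypot(coords[0, 1], coords[0, 2]) == pytest.approx(7.0, abs=1e-6)

    def test_round_trip_within_half_micron(self):
        rng = np.random.default_rng(4)
        c = self._centerline()
        pts = c.samples_um[rng.integers(0, 200, 40)] + rng.normal(0, 8, (40, 3))
        back = fg.from_centerline_coords(fg.to_centerline_coords(pts, c), c)
        assert np.linalg.norm(back - pts, axis=1).max() < 0.5


class TestSegments:
    def _setup(self):
        theta = np.linspace(0.2, 2.2, 100)
        c = fg.fit_centerline(quartic_points(theta))
        mask = fg.centerline_mask((16, 40, 40), (2, 2, 2), c, radius_um=20.0)
        return c, mask

    def test_labels_partition_mask_exactly(self):
        c, mask = self._setup()
        labels = fg.partition_segments(mask, (2, 2, 2), c, 4)
        assert np.array_equal(labels > 0, mask)
        assert set(np.unique(labels[mask])) <= {1, 2, 3, 4}

    def test_odd_segment_count_rejected(self):
        c, mask = self._setup()
        with pytest.raises(ValueError):
            fg.partition_segments(mask, (2, 2, 2), c, 3)

    def test_proximal_positive_offset_is_first_left_segment(self):
        c, _ = self._setup()
        e_lat = np.cross(c.tangents, c.plane_normal)
        e_lat /= np.linalg.norm(e_lat, axis=1, keepdims=True)
        idx = 40                                  # arc fraction ~0.2: proximal
        p = c.samples_um[idx] + 5.0 * e_lat[idx]
        mask = np.zeros((40, 60, 60), bool)
        vox = tuple(np.round(p / 2.0).astype(int))
        mask[vox] = True
        labels = fg.partition_segments(mask, (2, 2, 2), c, 4)
        assert labels[vox] == 1

    def test_segment_counts_sum_to_mask(self):
        c, mask = self._setup()
        labels = fg.partition_segments(mask, (2, 2, 2), c, 6)
        assert sum((labels == s).sum() for s in range(1, 7)) == mask.sum()


class TestSegmentStatistics:
    def _field_and_labels(self, seed=5):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, size=(5, 6, 7))
        vel = rng.normal(size=(3, 5, 6, 7, 3)) * 100
        vf = VectorField4D(vel, labels > 0, (2, 2, 2), 0.005)
        return vf, labels

    def test_matches_bruteforce_summation(self):
        vf, labels = self._field_and_labels()
        st = fg.segment_statistics(vf, labels)
        for t in range(vf.n_frames):
            v = vf.velocities[t]
            mag = np.linalg.norm(v, axis=-1)
            for s in (1, 2, 3, 4):
                sel = labels == s
                vs, ms = v[sel], mag[sel]
                row = st[(st.frame == t) & (st.segment == s)].iloc[0]
                assert np.allclose([row.mean_vz, row.mean_vy, row.mean_vx],
                                   vs.mean(axis=0), rtol=1e-9)
                assert np.allclose(
                    [row.wmean_vz, row.wmean_vy, row.wmean_vx],
                    (ms[:, None] * vs).sum(axis=0) / ms.sum(), rtol=1e-9,
                )
                assert row.mean_mag == pytest.approx(ms.mean(), rel=1e-12)
                assert row.global_mag == pytest.approx(
                    np.linalg.norm(v[labels > 0], axis=-1).mean(), rel=1e-12
                )

    def test_uniform_field_unit_relative_velocity(self):
        _, labels = self._field_and_labels()
        vel = np.zeros((2, 5, 6, 7, 3))
        vel[..., 1] = 4.0
        vf = VectorField4D(vel, labels > 0, (2, 2, 2), 0.005)
        st = fg.segment_statistics(vf, labels)
        assert np.allclose(st.rel_vel, 1.0)
        assert np.allclose(st.mean_mag, 4.0)

    def test_field_confined_to_one_segment(self):
        vf, labels = self._field_and_labels()
        vel = np.zeros_like(vf.velocities)
        vel[:, labels == 1] = 50.0
        vf2 = VectorField4D(vel, labels > 0, (2, 2, 2), 0.005)
        st = fg.segment_statistics(vf2, labels)
        assert (st[st.segment != 1].mean_mag == 0).all()
        assert (st[st.segment == 1].mean_mag > 0).all()

    def test_global_mag_is_count_weighted_segment_mean(self):
        vf, labels = self._field_and_labels()
        st = fg.segment_statistics(vf, labels)
        sub = st[st.frame == 0]
        weighted = (sub.mean_mag * sub.n_vox).sum() / sub.n_vox.sum()
        assert weighted == pytest.approx(sub.global_mag.iloc[0], rel=1e-12)

    def test_relative_velocity_by_phase_windows(self):
        vf, labels = self._field_and_labels()
        st = fg.segment_statistics(vf, labels)
        rel = fg.relative_velocity_by_phase(
            st, {"systole": (0, 1), "diastole": (2, 2)}
        )
        sub = st[(st.frame <= 1) & (st.segment == 2)]
        expected = sub.mean_mag.mean() / sub.global_mag.mean()
        got = rel[(rel.phase == "systole") & (rel.segment == 2)]
        assert got.relative_velocity.iloc[0] == pytest.approx(expected, rel=1e-12)


class TestRigidInvariance:
    def test_scalar_outputs_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(6)
        theta = np.linspace(0.2, 2.2, 120)
        pts = quartic_points(theta) + rng.normal(0, 0.5, (120, 3))
        av = pts[0]
        vel = rng.normal(0, 500, (120, 3))
        tracks = TrackSet([Track(0, np.arange(120), pts, vel)])

        R, t = random_rigid(7)
        pts_r = pts @ R.T + t
        tracks_r = TrackSet([Track(0, np.arange(120), pts_r, vel @ R.T)])

        cA = fg.fit_centerline(pts, av_point_um=av)
        cB = fg.fit_centerline(pts_r, av_point_um=av @ R.T + t)

        assert cA.total_length_um == pytest.approx(cB.total_length_um, rel=1e-6)
        assert np.linalg.norm(cA.residuals_um) == pytest.approx(
            np.linalg.norm(cB.residuals_um), rel=1e-6
        )
        sA = fg.project_flow_velocity(tracks, cA)
        sB = fg.project_flow_velocity(tracks_r, cB)
        assert np.allclose(sA.to_numpy(), sB.to_numpy(), rtol=1e-6, atol=1e-6)
        ccA = fg.to_centerline_coords(pts, cA)
        ccB = fg.to_centerline_coords(pts_r, cB)
        assert np.allclose(ccA[:, 0], ccB[:, 0], atol=1e-6)
        assert np.allclose(np.hypot(ccA[:, 1], ccA[:, 2]),
                           np.hypot(ccB[:, 1], ccB[:, 2]), atol=1e-6)


def test_default_phase_windows_cover_cycle():
    v = pd.Series(1000 * np.sin(2 * np.pi * np.arange(40) / 40 + 0.3))
    win = fg.default_phase_windows(v)
    assert set(win) == {"systole", "diastole"}
    a, b = win["systole"]
    peak = int(np.argmax(v.to_numpy()))
    frames = np.arange(a, b + 1) if a <= b else np.concatenate(
        [np.arange(a, 40), np.arange(0, b + 1)]
    )
    assert peak in frames
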