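"""Camera model, rectification, triangulation and refraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereoloc.geometry import (
    CameraExtrinsics,
    CameraIntrinsics,
    MediumConfig,
    OpticsConfig,
    StereoRig,
    correct_refraction,
    project_point,
    project_points,
    rectified_pixels,
    rectify_rig,
    symmetric_rig,
    triangulate,
    undistort_points,
)


def _random_volume_points(rng, n, half=(3.0, 3.0, 2.0)):
    return rng.uniform(-1, 1, size=(n, 3)) * np.array(half)


def _project_both(rig, X):
    uv1 = project_points(X, rig.cam1.intrinsics, rig.cam1.extrinsics)
    uv2 = project_points(X, rig.cam2.intrinsics, rig.cam2.extrinsics)
    return uv1, uv2


class TestProjection:
    def test_axial_point_maps_to_principal_point(self, rig):
        intr = rig.cam1.intrinsics
        # a point on the optical axis, at two different depths
        C = rig.cam1.extrinsics.center
        bore = rig.cam1.extrinsics.R[2]
        for depth in (150.0, 200.0):
            u, v = project_point(C + depth * bore, intr, rig.cam1.extrinsics)
            assert u == pytest.approx(intr.cx, abs=1e-9)
            assert v == pytest.approx(intr.cy, abs=1e-9)

    def test_zero_distortion_equals_pinhole(self, rig):
        rng = np.random.default_rng(0)
        X = _random_volume_points(rng, 50)
        e = rig.cam1.extrinsics
        intr = rig.cam1.intrinsics
        Xc = X @ e.R.T + e.t
        expected_u = intr.fx * Xc[:, 0] / Xc[:, 2] + intr.cx
        expected_v = intr.fy * Xc[:, 1] / Xc[:, 2] + intr.cy
        uv = project_points(X, intr, e)
        np.testing.assert_allclose(uv[:, 0], expected_u, atol=1e-12)
        np.testing.assert_allclose(uv[:, 1], expected_v, atol=1e-12)

    def test_point_behind_camera_raises(self, rig):
        behind = rig.cam1.extrinsics.center - rig.cam1.extrinsics.R[2]
        with pytest.raises(ValueError, match="behind"):
            project_point(behind, rig.cam1.intrinsics, rig.cam1.extrinsics)

    def test_axial_displacement_changes_disparity_as_predicted(self, rig):
        """100 um of depth moves the raw disparity by ~2 sin(20) * 100/40.5 px."""
        op_um = OpticsConfig().object_pixel_um
        dz = 0.1  # mm
        uv1a, uv2a = _project_both(rig, np.array([[0.0, 0.0, 0.0]]))
        uv1b, uv2b = _project_both(rig, np.array([[0.0, 0.0, dz]]))
        d_disp = abs(
            (uv1b[0, 0] - uv2b[0, 0]) - (uv1a[0, 0] - uv2a[0, 0])
        )
        expected = 2 * math.sin(math.radians(20)) * dz * 1e3 / op_um
        assert d_disp == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(1.69, abs=0.01)


class TestUndistortion:
    def test_principal_point_maps_to_zero(self, rig):
        intr = rig.cam1.intrinsics
        n = undistort_points([[intr.cx, intr.cy]], intr)
        np.testing.assert_allclose(n, 0.0, atol=1e-15)

    def test_closed_form_when_undistorted(self, rig):
        intr = rig.cam1.intrinsics
        pts = np.array([[100.0, 200.0], [639.0, 0.0]])
        n = undistort_points(pts, intr)
        np.testing.assert_allclose(n[:, 0], (pts[:, 0] - intr.cx) / intr.fx)
        np.testing.assert_allclose(n[:, 1], (pts[:, 1] - intr.cy) / intr.fy)

    def test_undistort_recovers_pinhole_normalized_coords(self, distorted_rig):
        rng = np.random.default_rng(1)
        X = _random_volume_points(rng, 200)
        e = distorted_rig.cam1.extrinsics
        intr = distorted_rig.cam1.intrinsics
        uv = project_points(X, intr, e)
        n = undistort_points(uv, intr)
        Xc = X @ e.R.T + e.t
        np.testing.assert_allclose(n, Xc[:, :2] / Xc[:, 2:3], atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        k1=st.floats(-0.5, 0.5),
        k2=st.floats(-0.2, 0.2),
        xn=st.floats(-0.3, 0.3),
        yn=st.floats(-0.3, 0.3),
    )
    def test_roundtrip_project_undistort(self, k1, k2, xn, yn):
        """project -> undistort round-trips within 1e-6 px for moderate k."""
        intr = CameraIntrinsics(800.0, 820.0, 320.0, 256.0, k1, k2)
        r2 = xn * xn + yn * yn
        f = 1.0 + k1 * r2 + k2 * r2 * r2
        # keep the distortion bijective on this radius range
        if f <= 0.3 or 1.0 + 3 * k1 * r2 + 5 * k2 * r2 * r2 <= 0.05:
            return
        u = intr.fx * xn * f + intr.cx
        v = intr.fy * yn * f + intr.cy
        n = undistort_points([[u, v]], intr)[0]
        assert abs(n[0] - xn) * intr.fx < 1e-6
        assert abs(n[1] - yn) * intr.fy < 1e-6


class TestRectification:
    def test_parallel_rig_rectification_is_identity(self):
        intr = CameraIntrinsics(1000.0, 1000.0, 320.0, 256.0)
        R = np.eye(3)
        cam1 = CameraExtrinsics(R, np.array([0.0, 0.0, 100.0]))
        cam2 = CameraExtrinsics(R, np.array([-20.0, 0.0, 100.0]))
        from stereoloc.geometry import Camera

        rig = rectify_rig(StereoRig(Camera(intr, cam1), Camera(intr, cam2), 0.0))
        np.testing.assert_allclose(rig.rect1, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(rig.rect2, np.eye(3), atol=1e-12)

    def test_symmetric_rig_rectification_angle_is_theta(self, rig):
        for rect in (rig.rect1, rig.rect2):
            angle = math.degrees(math.acos((np.trace(rect) - 1) / 2))
            assert angle == pytest.approx(20.0, abs=1e-9)

    def test_rectified_correspondences_are_horizontal(self, distorted_rig):
        rng = np.random.default_rng(2)
        X = _random_volume_points(rng, 1000)
        dv = []
        for cam_idx in (1, 2):
            cam = distorted_rig.camera(cam_idx)
            uv = project_points(X, cam.intrinsics, cam.extrinsics)
            n = undistort_points(uv, cam.intrinsics)
            dv.append(rectified_pixels(n, distorted_rig, cam_idx)[:, 1])
        assert np.max(np.abs(dv[0] - dv[1])) < 1e-6

    def test_zero_baseline_raises(self, rig):
        from stereoloc.geometry import Camera

        bad = StereoRig(rig.cam1, rig.cam1, 20.0)
        with pytest.raises(ValueError, match="baseline"):
            rectify_rig(bad)


class TestTriangulation:
    def test_noiseless_roundtrip(self, rig):
        rng = np.random.default_rng(3)
        X = _random_volume_points(rng, 500)
        uv1, uv2 = _project_both(rig, X)
        n1 = undistort_points(uv1, rig.cam1.intrinsics)
        n2 = undistort_points(uv2, rig.cam2.intrinsics)
        P, gap = triangulate(n1, n2, rig)
        assert np.max(np.abs(P - X)) < 1e-6
        assert np.max(gap) < 1e-6

    def test_larger_disparity_means_nearer_monotonically(self, rig):
        zs = np.linspace(-2.0, 2.0, 41)
        X = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
        uv1, uv2 = _project_both(rig, X)
        disparity = uv1[:, 0] - uv2[:, 0]
        # disparity decreases strictly with depth: larger disparity = nearer
        assert np.all(np.diff(disparity) < 0)

    def test_near_parallel_rays_raise(self, rig):
        # identical cameras -> parallel rays for equal pixels
        bad = StereoRig(rig.cam1, rig.cam1, 20.0)
        with pytest.raises(ValueError, match="parallel"):
            triangulate([[0.0, 0.0]], [[0.0, 0.0]], bad)

    def test_axial_scan_recovers_step(self, rig):
        """A plane translated axially in 5 um steps: recovered mean step
        matches the scan step (noiseless)."""
        steps_mm = 0.005
        grid = np.stack(
            np.meshgrid(np.linspace(-2, 2, 5), np.linspace(-2, 2, 5)), axis=-1
        ).reshape(-1, 2)
        z_means = []
        for i in range(5):
            X = np.column_stack([grid, np.full(len(grid), i * steps_mm)])
            uv1, uv2 = _project_both(rig, X)
            P, _ = triangulate(
                undistort_points(uv1, rig.cam1.intrinsics),
                undistort_points(uv2, rig.cam2.intrinsics),
                rig,
            )
            z_means.append(P[:, 2].mean())
        np.testing.assert_allclose(np.diff(z_means), steps_mm, rtol=1e-6)


class TestRefraction:
    def test_extent_scaling(self):
        medium = MediumConfig(refractive_index=1.33, interface_z=0.0)
        assert correct_refraction(0.1, medium) == pytest.approx(0.133)
        assert correct_refraction(0.0, medium) == 0.0

    def test_unit_index_is_identity(self):
        medium = MediumConfig(refractive_index=1.0, interface_z=0.0)
        pts = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, -1.0]])
        np.testing.assert_array_equal(correct_refraction(pts, medium), pts)

    def test_points_above_interface_unchanged(self):
        medium = MediumConfig(refractive_index=1.33, interface_z=1.0)
        pts = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 2.0]])
        out = correct_refraction(pts, medium)
        assert out[0, 2] == 0.5
        assert out[1, 2] == pytest.approx(1.0 + 1.33 * 1.0)

    def test_linear_and_order_independent_with_z_differences(self):
        medium = MediumConfig(refractive_index=1.33, interface_z=0.0)
        z1, z2 = 0.8, 2.1
        a = correct_refraction(np.array([[0, 0, z2]]), medium)[0, 2]
        b = correct_refraction(np.array([[0, 0, z1]]), medium)[0, 2]
        assert a - b == pytest.approx(correct_refraction(z2 - z1, medium))


class TestInvariants:
    def test_roundtrip_ten_thousand_points(self, distorted_rig):
        rng = np.random.default_rng(4)
        X = _random_volume_points(rng, 10_000)
        uv1, uv2 = _project_both(distorted_rig, X)
        P, _ = triangulate(
            undistort_points(uv1, distorted_rig.cam1.intrinsics),
            undistort_points(uv2, distorted_rig.cam2.intrinsics),
            distorted_rig,
        )
        assert np.max(np.abs(P - X)) < 1e-6

    def test_disparity_depth_slope_matches_vergence_formula(self, rig):
        op_um = OpticsConfig().object_pixel_um
        dz = 1e-3
        uv1a, uv2a = _project_both(rig, np.array([[0.0, 0.0, 0.0]]))
        uv1b, uv2b = _project_both(rig, np.array([[0.0, 0.0, dz]]))
        slope = abs(
            ((uv1b[0, 0] - uv2b[0, 0]) - (uv1a[0, 0] - uv2a[0, 0])) / dz
        )
        expected = 2 * math.sin(math.radians(20)) / (op_um * 1e-3)
        assert slope == pytest.approx(expected, rel=0.02)

    def test_invariants_of_dataclasses(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(-1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            CameraExtrinsics(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            MediumConfig(refractive_index=0.9)
        opt = OpticsConfig()
        assert opt.object_pixel_um == opt.pixel_pitch_um / opt.magnification
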