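"""Camera geometry for the dual-view rig.

A pinhole model with two-coefficient radial distortion per camera, a
symmetric stereo arrangement (the two optical axes verge at +/-theta
about the vertical axis), epipolar rectification, midpoint-of-rays
triangulation, and the flat-interface refractive depth rescale.

World frame convention
----------------------
Origin at the intersection of the two optical axes (the nominal focal
plane), ``z`` pointing away from the cameras along the bisector of the
two boresights (so depth into the sample increases with ``z``), ``x``
horizontal along the baseline, ``y`` vertical.  Pixels are 0-based with
pixel centers at integer coordinates; ``u`` is the column, ``v`` the row.
All world lengths are in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "CameraExtrinsics",
    "Camera",
    "StereoRig",
    "OpticsConfig",
    "MediumConfig",
    "project_point",
    "project_points",
    "undistort_points",
    "rectify_rig",
    "rectified_pixels",
    "triangulate",
    "correct_refraction",
    "symmetric_rig",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with two radial distortion coefficients.

    fx, fy, cx, cy are in pixels; k1, k2 are dimensionless coefficients
    of the radial factor ``1 + k1 r^2 + k2 r^4`` applied to normalized
    image coordinates.  Skew is fixed at zero.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class CameraExtrinsics:
    """World-to-camera rigid transform: ``x_cam = R @ x_world + t``.

    t is in mm.  R must be a proper rotation (orthonormal, det +1).
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("R must have determinant +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.R.T @ self.t


@dataclass(frozen=True)
class Camera:
    intrinsics: CameraIntrinsics
    extrinsics: CameraExtrinsics


@dataclass(frozen=True)
class OpticsConfig:
    """Detection-path optics; defaults match the SWIR dual-camera setup."""

    magnification: float = 0.37
    pixel_pitch_um: float = 15.0
    sensor_width: int = 640
    sensor_height: int = 512

    @property
    def object_pixel_um(self) -> float:
        """Pixel footprint in the object plane (µm) = pitch / magnification."""
        return self.pixel_pitch_um / self.magnification


@dataclass(frozen=True)
class MediumConfig:
    """Immersion medium for the flat-interface depth rescale.

    Depth extents below ``interface_z`` (world z of the air/medium
    boundary, mm) are stretched by ``refractive_index``; lateral
    coordinates are unchanged.  This is a scalar rescale, not refractive
    ray tracing.
    """

    refractive_index: float = 1.33
    interface_z: float = 0.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass
class StereoRig:
    """Two calibrated cameras plus (optional) rectification transforms.

    ``rect1``/``rect2`` rotate camera-frame ray directions into a common
    rectified orientation whose x-axis lies along the baseline;
    ``rect_intrinsics`` are the shared rectified pinhole intrinsics
    (distortion-free).  Populate them with :func:`rectify_rig`.
    """

    cam1: Camera
    cam2: Camera
    theta_deg: float = 20.0
    rect1: np.ndarray | None = None
    rect2: np.ndarray | None = None
    rect_intrinsics: CameraIntrinsics | None = None

    @property
    def baseline(self) -> float:
        return float(
            np.linalg.norm(self.cam2.extrinsics.center - self.cam1.extrinsics.center)
        )

    def camera(self, index: int) -> Camera:
        if index == 1:
            return self.cam1
        if index == 2:
            return self.cam2
        raise IndexError("camera index must be 1 or 2")


# ---------------------------------------------------------------------------
# projection / undistortion


def _distort(xn: np.ndarray, yn: np.ndarray, intr: CameraIntrinsics):
    r2 = xn * xn + yn * yn
    f = 1.0 + intr.k1 * r2 + intr.k2 * r2 * r2
    return xn * f, yn * f


def project_points(
    X: np.ndarray, intr: CameraIntrinsics, extr: CameraExtrinsics
) -> np.ndarray:
    """Project world points (N, 3) mm to pixel coordinates (N, 2).

    Pinhole projection of the normalized camera-frame point, radially
    distorted by ``1 + k1 r^2 + k2 r^4``, then scaled/shifted by the
    focal lengths and principal point.  Points at or behind the camera
    plane raise ``ValueError``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X @ extr.R.T + extr.t
    z = Xc[:, 2]
    if np.any(z <= 0):
        raise ValueError("point at or behind the camera plane (camera-frame z <= 0)")
    xn = Xc[:, 0] / z
    yn = Xc[:, 1] / z
    xd, yd = _distort(xn, yn, intr)
    uv = np.stack([intr.fx * xd + intr.cx, intr.fy * yd + intr.cy], axis=1)
    return uv


def project_point(
    X, intr: CameraIntrinsics, extr: CameraExtrinsics
) -> tuple[float, float]:
    """Single-point convenience wrapper around :func:`project_points`."""
    uv = project_points(np.asarray(X, dtype=float).reshape(1, 3), intr, extr)
    return float(uv[0, 0]), float(uv[0, 1])


def undistort_points(
    points: np.ndarray,
    intr: CameraIntrinsics,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Invert the radial distortion: pixels (N, 2) -> normalized coords (N, 2).

    Uses damped fixed-point iteration x_{k+1} = x_d / (1 + k1 r_k^2 + k2 r_k^4)
    starting from the distorted normalized coordinates.  Raises
    ``RuntimeError`` naming the first non-converged point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xd = (pts[:, 0] - intr.cx) / intr.fx
    yd = (pts[:, 1] - intr.cy) / intr.fy
    if intr.k1 == 0.0 and intr.k2 == 0.0:
        return np.stack([xd, yd], axis=1)
    x, y = xd.copy(), yd.copy()
    converged = np.zeros(len(x), dtype=bool)
    for _ in range(max_iter):
        r2 = x * x + y * y
        f = 1.0 + intr.k1 * r2 + intr.k2 * r2 * r2
        x_new = xd / f
        y_new = yd / f
        step = np.hypot(x_new - x, y_new - y)
        x, y = x_new, y_new
        converged = step < tol
        if converged.all():
            break
    if not converged.all():
        bad = int(np.flatnonzero(~converged)[0])
        raise RuntimeError(
            f"undistortion did not converge for point {bad}: "
            f"({pts[bad, 0]:.3f}, {pts[bad, 1]:.3f})"
        )
    return np.stack([x, y], axis=1)


# ---------------------------------------------------------------------------
# rectification


def rectify_rig(rig: StereoRig) -> StereoRig:
    """Populate the rectification transforms of a calibrated rig.

    Both cameras are rotated to a common orientation whose x-axis lies
    along the baseline (so corresponding rectified points share the
    vertical coordinate), whose z-axis is the mean boresight projected
    orthogonal to the baseline.  Shared rectified intrinsics use the mean
    focal length and the sensor-center principal point.
    """
    C1 = rig.cam1.extrinsics.center
    C2 = rig.cam2.extrinsics.center
    b = C2 - C1
    bn = float(np.linalg.norm(b))
    if bn < 1e-12:
        raise ValueError("zero baseline: cameras are coincident")
    x_r = b / bn
    z_mean = rig.cam1.extrinsics.R[2] + rig.cam2.extrinsics.R[2]
    z_r = z_mean - (z_mean @ x_r) * x_r
    z_norm = float(np.linalg.norm(z_r))
    if z_norm < 1e-12:
        raise ValueError("degenerate rig: mean boresight parallel to baseline")
    z_r /= z_norm
    y_r = np.cross(z_r, x_r)
    R_common = np.stack([x_r, y_r, z_r])  # world -> rectified orientation

    i1, i2 = rig.cam1.intrinsics, rig.cam2.intrinsics
    f = 0.25 * (i1.fx + i1.fy + i2.fx + i2.fy)
    cx = 0.5 * (i1.cx + i2.cx)
    cy = 0.5 * (i1.cy + i2.cy)
    rect_intr = CameraIntrinsics(fx=f, fy=f, cx=cx, cy=cy)

    rig.rect1 = R_common @ rig.cam1.extrinsics.R.T
    rig.rect2 = R_common @ rig.cam2.extrinsics.R.T
    rig.rect_intrinsics = rect_intr
    return rig


def rectified_pixels(
    normalized: np.ndarray, rig: StereoRig, camera: int
) -> np.ndarray:
    """Map undistorted normalized coords (N, 2) to rectified pixel coords.

    Requires :func:`rectify_rig` to have been called on ``rig``.
    """
    if rig.rect1 is None or rig.rect_intrinsics is None:
        raise ValueError("rig has no rectification transforms; call rectify_rig first")
    rect = rig.rect1 if camera == 1 else rig.rect2
    pts = np.atleast_2d(np.asarray(normalized, dtype=float))
    dirs = np.column_stack([pts, np.ones(len(pts))]) @ rect.T
    ri = rig.rect_intrinsics
    u = ri.fx * dirs[:, 0] / dirs[:, 2] + ri.cx
    v = ri.fy * dirs[:, 1] / dirs[:, 2] + ri.cy
    return np.stack([u, v], axis=1)


# ---------------------------------------------------------------------------
# triangulation


def triangulate(
    p1: np.ndarray, p2: np.ndarray, rig: StereoRig
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate undistorted normalized correspondences to world points.

    Back-projects each point to a ray and returns the midpoint of the
    shortest segment between the two rays, plus the skew distance (ray
    gap, mm) as a quality metric.  Near-parallel rays raise ``ValueError``.

    Parameters
    ----------
    p1, p2 : (N, 2) undistorted normalized coordinates in camera 1 / 2.

    Returns
    -------
    points : (N, 3) world coordinates in mm.
    gap : (N,) distance between the two rays at closest approach, mm.
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    e1, e2 = rig.cam1.extrinsics, rig.cam2.extrinsics
    C1, C2 = e1.center, e2.center
    d1 = np.column_stack([p1, np.ones(len(p1))]) @ e1.R
    d2 = np.column_stack([p2, np.ones(len(p2))]) @ e2.R
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
    w0 = C1 - C2
    b = np.einsum("ij,ij->i", d1, d2)
    dd = d1 @ w0
    ee = d2 @ w0
    denom = 1.0 - b * b  # a = c = 1 for unit directions
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("near-parallel rays: triangulation is ill-conditioned")
    s = (b * ee - dd) / denom
    t = (ee - b * dd) / denom
    P1 = C1 + s[:, None] * d1
    P2 = C2 + t[:, None] * d2
    points = 0.5 * (P1 + P2)
    gap = np.linalg.norm(P1 - P2, axis=1)
    return points, gap


# ---------------------------------------------------------------------------
# refraction


def correct_refraction(points, medium: MediumConfig):
    """Rescale apparent depth below a flat air/medium interface.

    For world points (N, 3) or (3,), the z-extent below ``interface_z``
    is multiplied by the refractive index; points above the interface and
    lateral coordinates are unchanged.  A scalar input is treated as a
    z-extent and simply multiplied by the index.
    """
    n = medium.refractive_index
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 0:
        return float(arr) * n
    pts = np.atleast_2d(arr).copy()
    below = pts[:, 2] > medium.interface_z
    pts[below, 2] = medium.interface_z + n * (pts[below, 2] - medium.interface_z)
    return pts.reshape(arr.shape)


# ---------------------------------------------------------------------------
# rig construction


def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def symmetric_rig(
    theta_deg: float = 20.0,
    optics: OpticsConfig | None = None,
    *,
    focal_length_mm: float = 50.0,
    k1: float = 0.0,
    k2: float = 0.0,
    rectify: bool = True,
) -> StereoRig:
    """Build the nominal symmetric rig: two cameras at +/-theta vergence.

    The working distance and pixel focal length follow from the lens
    focal length and the magnification (thin-lens conjugates), so that
    one sensor pixel spans ``pixel_pitch / magnification`` in the object
    plane at the axes' crossing point.
    """
    optics = optics or OpticsConfig()
    M = optics.magnification
    image_dist_mm = focal_length_mm * (1.0 + M)
    working_dist_mm = image_dist_mm / M
    f_px = image_dist_mm / (optics.pixel_pitch_um * 1e-3)
    th = math.radians(theta_deg)

    cams = []
    for sign in (+1.0, -1.0):
        # boresight from camera toward the world origin
        bore = np.array([sign * math.sin(th), 0.0, math.cos(th)])
        C = -working_dist_mm * bore
        x_cam = np.cross(np.array([0.0, 1.0, 0.0]), bore)
        x_cam /= np.linalg.norm(x_cam)
        y_cam = np.cross(bore, x_cam)
        R = np.stack([x_cam, y_cam, bore])
        t = -R @ C
        intr = CameraIntrinsics(
            fx=f_px,
            fy=f_px,
            cx=(optics.sensor_width - 1) / 2.0,
            cy=(optics.sensor_height - 1) / 2.0,
            k1=k1,
            k2=k2,
        )
        cams.append(Camera(intr, CameraExtrinsics(R, t)))

    rig = StereoRig(cam1=cams[0], cam2=cams[1], theta_deg=theta_deg)
    if rectify:
        rectify_rig(rig)
    return rig
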