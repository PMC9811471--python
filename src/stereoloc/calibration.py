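"""Stereo camera calibration from checkerboard views.

A classical object-based pipeline: detect inner checkerboard corners
with sub-pixel refinement, initialize each camera's intrinsics from
view homographies (closed form), then jointly refine intrinsics, the
two-coefficient radial distortion, per-view board poses and the
inter-camera pose by nonlinear least squares on the reprojection error.

Skew is fixed at zero; fx and fy are estimated independently.  Board
poses are parameterized as axis-angle rotation vectors.  All corners
are weighted equally (no outlier rejection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (
    Camera,
    CameraExtrinsics,
    CameraIntrinsics,
    StereoRig,
    project_points,
    rectify_rig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CheckerboardSpec",
    "CalibrationView",
    "CalibrationResult",
    "CornerDetectionError",
    "DegenerateGeometryError",
    "board_points",
    "detect_corners",
    "calibrate_camera",
    "calibrate_stereo",
    "reprojection_error",
]


class CornerDetectionError(RuntimeError):
    """Raised when the expected corner grid cannot be extracted."""


class DegenerateGeometryError(RuntimeError):
    """Raised when the view geometry cannot constrain the calibration."""


@dataclass(frozen=True)
class CheckerboardSpec:
    """Inner-corner grid of a printed checkerboard.

    ``inner_rows x inner_cols`` counts the interior corners (one less
    per axis than the square count); ``square_size_mm`` is the square
    side length.
    """

    inner_rows: int
    inner_cols: int
    square_size_mm: float

    def __post_init__(self) -> None:
        if self.inner_rows < 2 or self.inner_cols < 2:
            raise ValueError("need at least a 2x2 inner-corner grid")
        if self.square_size_mm <= 0:
            raise ValueError("square size must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_rows * self.inner_cols


@dataclass
class CalibrationView:
    """Detected corners of one stereo view, ordered row-major.

    ``corners2`` may be None for single-camera calibration.  Corner
    order must be identical across cameras.
    """

    corners1: np.ndarray
    corners2: np.ndarray | None = None
    view_id: int = 0


@dataclass
class CalibrationResult:
    rig: StereoRig
    mean_reprojection_error_px: float
    per_view_errors_px: np.ndarray
    board_poses: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def board_points(spec: CheckerboardSpec) -> np.ndarray:
    """Board-frame 3D corner coordinates (N, 3), row-major, z = 0, mm."""
    r, c = np.mgrid[0 : spec.inner_rows, 0 : spec.inner_cols]
    pts = np.zeros((spec.n_corners, 3))
    pts[:, 0] = c.ravel() * spec.square_size_mm
    pts[:, 1] = r.ravel() * spec.square_size_mm
    return pts


# ---------------------------------------------------------------------------
# corner detection


def _order_grid(corners: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Order scattered grid corners row-major along the board axes.

    Projects the points onto their principal axes, assigns rows by the
    axis that yields ``rows`` well-separated groups of ``cols`` points,
    then canonicalizes so the first corner is nearest the image
    top-left (flipping row/column order as needed; a 180-degree board
    rotation maps to the same ordering).
    """
    centered = corners - corners.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T  # axis 0 = largest spread

    def try_group(row_axis: int) -> np.ndarray | None:
        col_axis = 1 - row_axis
        order = np.argsort(proj[:, row_axis], kind="stable")
        if len(order) != rows * cols:
            return None
        grid = order.reshape(rows, cols)
        # rows must be separated: max within-row spread along row_axis
        # smaller than min between-row gap
        row_vals = proj[grid, row_axis]
        within = row_vals.max(axis=1) - row_vals.min(axis=1)
        means = row_vals.mean(axis=1)
        gaps = np.diff(means)
        if len(gaps) and within.max() >= np.abs(gaps).min():
            return None
        for r in range(rows):
            grid[r] = grid[r][np.argsort(proj[grid[r], col_axis], kind="stable")]
        return grid

    grid = try_group(1)
    if grid is None:
        grid = try_group(0)
    if grid is None:
        raise CornerDetectionError("could not organize corners into a grid")

    # canonicalize: first corner nearest the image top-left
    best = None
    for flip_r in (False, True):
        for flip_c in (False, True):
            g = grid[::-1] if flip_r else grid
            g = g[:, ::-1] if flip_c else g
            first = corners[g[0, 0]]
            key = (first[0] + first[1], first[0])
            if best is None or key < best[0]:
                best = (key, g.copy())
    return corners[best[1].ravel()]


def detect_corners(image: np.ndarray, spec: CheckerboardSpec) -> np.ndarray:
    """Detect the inner corners of a checkerboard in a single frame.

    A quadrant-contrast response (checkerboard saddle template) -> peak
    picking -> Foerstner sub-pixel refinement, then grid ordering.
    Only interior black/white crossings respond strongly, so corners of
    the board outline are ignored.  Deterministic for a fixed image.
    Raises :class:`CornerDetectionError` when the expected corner count
    cannot be found.
    """
    from scipy import ndimage
    from skimage.feature import corner_peaks, corner_subpix

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2D frame")
    rng = img.max() - img.min()
    if rng <= 0:
        raise CornerDetectionError("uniform image: no corners present")
    img = (img - img.min()) / rng

    m = 5  # quadrant half-size, px
    kernel = np.ones((2 * m, 2 * m))
    kernel[:m, m:] = -1.0
    kernel[m:, :m] = -1.0
    response = np.abs(ndimage.convolve(img, kernel, mode="reflect"))
    peaks = corner_peaks(
        response, min_distance=5, threshold_rel=0.2, num_peaks=spec.n_corners
    )
    if len(peaks) != spec.n_corners:
        raise CornerDetectionError(
            f"found {len(peaks)} corners, expected {spec.n_corners}"
        )
    refined = corner_subpix(img, peaks.astype(float), window_size=13)
    bad = np.isnan(refined).any(axis=1)
    refined[bad] = peaks[bad]
    corners_uv = refined[:, ::-1]  # (row, col) -> (u, v)
    return _order_grid(corners_uv, spec.inner_rows, spec.inner_cols)


# ---------------------------------------------------------------------------
# Zhang-style closed-form initialization


def _normalize_for_dlt(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - mean, axis=1)), 1e-12)
    T = np.array(
        [[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1.0]]
    )
    return (pts - mean) * scale, T


def _homography(obj_xy: np.ndarray, img_uv: np.ndarray) -> np.ndarray:
    """DLT homography mapping board-plane (x, y) to pixels (u, v)."""
    src, Ts = _normalize_for_dlt(obj_xy)
    dst, Td = _normalize_for_dlt(img_uv)
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    A[0::2, 0] = -x
    A[0::2, 1] = -y
    A[0::2, 2] = -1
    A[0::2, 6] = u * x
    A[0::2, 7] = u * y
    A[0::2, 8] = u
    A[1::2, 3] = -x
    A[1::2, 4] = -y
    A[1::2, 5] = -1
    A[1::2, 6] = v * x
    A[1::2, 7] = v * y
    A[1::2, 8] = v
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    """Constraint row for h_i^T B h_j with zero-skew symmetric B.

    B is parameterized as [B11, B22, B13, B23, B33] (B12 = 0).
    """
    hi, hj = H[:, i], H[:, j]
    return np.array(
        [
            hi[0] * hj[0],
            hi[1] * hj[1],
            hi[0] * hj[2] + hi[2] * hj[0],
            hi[1] * hj[2] + hi[2] * hj[1],
            hi[2] * hj[2],
        ]
    )


def _intrinsics_from_homographies(Hs: list[np.ndarray]) -> CameraIntrinsics:
    rows = []
    for H in Hs:
        rows.append(_vij(H, 0, 1))
        rows.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    A = np.stack(rows)
    _, s, vt = np.linalg.svd(A)
    b = vt[-1]
    b1, b2, b3, b4, b5 = b
    if b1 * b5 < 0 or b2 * b5 < 0:
        b = -b
        b1, b2, b3, b4, b5 = b
    lam = b5 - (b3 * b3 / b1 + b4 * b4 / b2)
    fx2, fy2 = lam / b1, lam / b2
    if fx2 <= 0 or fy2 <= 0:
        raise DegenerateGeometryError(
            "closed-form intrinsics failed: board orientations are degenerate"
        )
    return CameraIntrinsics(
        fx=float(np.sqrt(fx2)),
        fy=float(np.sqrt(fy2)),
        cx=float(-b3 / b1),
        cy=float(-b4 / b2),
    )


def _pose_from_homography(
    H: np.ndarray, intr: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray]:
    Kinv = np.linalg.inv(intr.K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.stack([r1, r2, r3], axis=1)
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R, t


def _rvec(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(R).as_rotvec()


def _rmat(rvec: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(rvec).as_matrix()


def _project_param(
    obj: np.ndarray, intr_vec: np.ndarray, rvec: np.ndarray, t: np.ndarray
) -> np.ndarray:
    fx, fy, cx, cy, k1, k2 = intr_vec
    Xc = obj @ _rmat(rvec).T + t
    xn = Xc[:, 0] / Xc[:, 2]
    yn = Xc[:, 1] / Xc[:, 2]
    r2 = xn * xn + yn * yn
    f = 1.0 + k1 * r2 + k2 * r2 * r2
    return np.stack([fx * xn * f + cx, fy * yn * f + cy], axis=1)


# ---------------------------------------------------------------------------
# single-camera calibration


def calibrate_camera(
    corner_sets: list[np.ndarray], spec: CheckerboardSpec
) -> tuple[CameraIntrinsics, list[tuple[np.ndarray, np.ndarray]]]:
    """Calibrate one camera from ordered corner sets of >= 3 board views.

    Closed-form initialization of fx, fy, cx, cy from view homographies
    (k1 = k2 = 0 initially) followed by joint Levenberg-Marquardt
    refinement of intrinsics, distortion and the per-view board poses.

    Returns the refined intrinsics and the per-view (R, t) board poses
    (board frame to camera frame).
    """
    if len(corner_sets) < 3:
        raise DegenerateGeometryError(
            f"need at least 3 views, got {len(corner_sets)}"
        )
    obj = board_points(spec)
    for i, c in enumerate(corner_sets):
        if len(c) != spec.n_corners:
            raise ValueError(f"view {i}: expected {spec.n_corners} corners")

    Hs = [_homography(obj[:, :2], np.asarray(c, dtype=float)) for c in corner_sets]
    intr0 = _intrinsics_from_homographies(Hs)
    poses0 = [_pose_from_homography(H, intr0) for H in Hs]

    n_views = len(corner_sets)
    x0 = np.concatenate(
        [np.array([intr0.fx, intr0.fy, intr0.cx, intr0.cy, 0.0, 0.0])]
        + [np.concatenate([_rvec(R), t]) for R, t in poses0]
    )
    observed = np.concatenate([np.asarray(c, dtype=float) for c in corner_sets])

    def residuals(x: np.ndarray) -> np.ndarray:
        intr_vec = x[:6]
        out = []
        for v in range(n_views):
            p = x[6 + 6 * v : 12 + 6 * v]
            out.append(_project_param(obj, intr_vec, p[:3], p[3:]))
        return (np.concatenate(out) - observed).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    intr = CameraIntrinsics(*sol.x[:6])
    poses = [
        (_rmat(sol.x[6 + 6 * v : 9 + 6 * v]), sol.x[9 + 6 * v : 12 + 6 * v])
        for v in range(n_views)
    ]
    logger.info(
        "camera calibration: %d views, rms residual %.4f px",
        n_views,
        np.sqrt(np.mean(sol.fun**2)),
    )
    return intr, poses


# ---------------------------------------------------------------------------
# stereo calibration


def _mean_rotation(Rs: list[np.ndarray]) -> np.ndarray:
    """Chordal mean: projection of the matrix average onto SO(3)."""
    M = np.mean(Rs, axis=0)
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def _rig_from_relative_pose(
    intr1: CameraIntrinsics,
    intr2: CameraIntrinsics,
    R_rel: np.ndarray,
    t_rel: np.ndarray,
) -> StereoRig:
    """Express the two cameras in the canonical world frame.

    The canonical frame has its origin at the closest approach of the
    two optical axes, z along the bisector of the boresights and x along
    the baseline component orthogonal to z.
    """
    # camera 1 frame doubles as the working frame
    C1 = np.zeros(3)
    C2 = -R_rel.T @ t_rel
    b1 = np.array([0.0, 0.0, 1.0])
    b2 = R_rel.T @ np.array([0.0, 0.0, 1.0])
    # closest point between the two optical axes
    w0 = C1 - C2
    bdot = b1 @ b2
    denom = 1.0 - bdot * bdot
    if denom < 1e-14:
        raise DegenerateGeometryError("optical axes are parallel; vergence is zero")
    s = (bdot * (b2 @ w0) - (b1 @ w0)) / denom
    u = ((b2 @ w0) - bdot * (b1 @ w0)) / denom
    origin = 0.5 * ((C1 + s * b1) + (C2 + u * b2))
    z_w = b1 + b2
    z_w = z_w / np.linalg.norm(z_w)
    x_w = (C2 - C1) - ((C2 - C1) @ z_w) * z_w
    x_w = x_w / np.linalg.norm(x_w)
    y_w = np.cross(z_w, x_w)
    W = np.stack([x_w, y_w, z_w])  # rows: world axes in cam1 coordinates

    theta = 0.5 * np.degrees(np.arccos(np.clip(b1 @ b2, -1.0, 1.0)))

    cams = []
    for Ri, ti in ((np.eye(3), np.zeros(3)), (R_rel, t_rel)):
        R_w = Ri @ W.T
        t_w = Ri @ origin + ti
        cams.append((R_w, t_w))
    rig = StereoRig(
        cam1=Camera(intr1, CameraExtrinsics(*cams[0])),
        cam2=Camera(intr2, CameraExtrinsics(*cams[1])),
        theta_deg=float(theta),
    )
    return rectify_rig(rig)


def calibrate_stereo(
    views: list[CalibrationView], spec: CheckerboardSpec
) -> CalibrationResult:
    """Jointly calibrate both cameras and their relative pose.

    Per-camera Zhang initialization, relative pose initialized by
    rotation-averaging the per-view pose compositions, then a joint
    bundle refinement over both intrinsics, both distortion pairs, the
    relative pose and the per-view board poses (expressed in camera 1).
    Returns a rectified :class:`~stereoloc.geometry.StereoRig` and the
    mean reprojection error over all corners, views and cameras.
    """
    if not views:
        raise DegenerateGeometryError("no views supplied")
    for v in views:
        if v.corners2 is None:
            raise ValueError(f"view {v.view_id}: second camera corners missing")
        if len(v.corners1) != spec.n_corners or len(v.corners2) != spec.n_corners:
            raise ValueError(f"view {v.view_id}: corner count mismatch")

    obj = board_points(spec)
    intr1, poses1 = calibrate_camera([v.corners1 for v in views], spec)
    intr2, poses2 = calibrate_camera([v.corners2 for v in views], spec)

    R_rel = _mean_rotation([R2 @ R1.T for (R1, _), (R2, _) in zip(poses1, poses2)])
    t_rel = np.mean(
        [t2 - R_rel @ t1 for (_, t1), (_, t2) in zip(poses1, poses2)], axis=0
    )

    n_views = len(views)
    x0 = np.concatenate(
        [
            np.array([intr1.fx, intr1.fy, intr1.cx, intr1.cy, intr1.k1, intr1.k2]),
            np.array([intr2.fx, intr2.fy, intr2.cx, intr2.cy, intr2.k1, intr2.k2]),
            _rvec(R_rel),
            t_rel,
        ]
        + [np.concatenate([_rvec(R), t]) for R, t in poses1]
    )
    obs1 = np.concatenate([np.asarray(v.corners1, dtype=float) for v in views])
    obs2 = np.concatenate([np.asarray(v.corners2, dtype=float) for v in views])
    observed = np.concatenate([obs1, obs2])

    def residuals(x: np.ndarray) -> np.ndarray:
        i1, i2 = x[:6], x[6:12]
        Rr, tr = _rmat(x[12:15]), x[15:18]
        out1, out2 = [], []
        for v in range(n_views):
            p = x[18 + 6 * v : 24 + 6 * v]
            Rb, tb = _rmat(p[:3]), p[3:]
            out1.append(_project_param(obj, i1, p[:3], tb))
            Xc2_R = Rr @ Rb
            out2.append(
                _project_param(obj, i2, _rvec(Xc2_R), Rr @ tb + tr)
            )
        return (np.concatenate(out1 + out2) - observed).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    x = sol.x
    intr1 = CameraIntrinsics(*x[:6])
    intr2 = CameraIntrinsics(*x[6:12])
    rig = _rig_from_relative_pose(intr1, intr2, _rmat(x[12:15]), x[15:18])

    res = sol.fun.reshape(-1, 2)
    per_corner = np.linalg.norm(res, axis=1)
    n = spec.n_corners
    per_view = np.array(
        [
            0.5
            * (
                per_corner[v * n : (v + 1) * n].mean()
                + per_corner[(n_views + v) * n : (n_views + v + 1) * n].mean()
            )
            for v in range(n_views)
        ]
    )
    board_poses = [
        (_rmat(x[18 + 6 * v : 21 + 6 * v]), x[21 + 6 * v : 24 + 6 * v])
        for v in range(n_views)
    ]
    result = CalibrationResult(
        rig=rig,
        mean_reprojection_error_px=float(per_corner.mean()),
        per_view_errors_px=per_view,
        board_poses=board_poses,
    )
    logger.info(
        "stereo calibration: %d views, mean reprojection error %.4f px",
        n_views,
        result.mean_reprojection_error_px,
    )
    return result


def reprojection_error(
    result: CalibrationResult, views: list[CalibrationView], spec: CheckerboardSpec
) -> float:
    """Mean Euclidean reprojection residual (px) of a calibration result.

    Board poses come from the result; detected corners from ``views``.
    """
    obj = board_points(spec)
    rig = result.rig
    errs = []
    for v, (Rb, tb) in zip(views, result.board_poses):
        # board pose is stored in the camera-1 frame
        for cam, corners in ((rig.cam1, v.corners1), (rig.cam2, v.corners2)):
            if corners is None:
                continue
            e = cam.extrinsics
            # world->cam composed with (cam1->world) applied to board pose
            R1, t1 = rig.cam1.extrinsics.R, rig.cam1.extrinsics.t
            # board->world: invert cam1's world->cam applied to board->cam1
            Rw = R1.T @ Rb
            tw = R1.T @ (tb - t1)
            X = obj @ Rw.T + tw
            uv = project_points(X, cam.intrinsics, e)
            errs.append(np.linalg.norm(uv - corners, axis=1))
    return float(np.concatenate(errs).mean())
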