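"""Synthetic dual-view scenes with exact ground truth.

Generates the study's characterization scenes — a static droplet, an
axially scanned checkerboard, a tilted tube, a knot of micro-tubing and
a cortical vessel network — as parametric centerlines, advects
fluorescent micro-droplets along them, and renders frame-synchronized
image stacks for both cameras through the full projection model.

The scattering forward model is deliberately simple and monotone: the
object-plane PSF width grows linearly with depth below the medium
interface and the collected signal decays exponentially.  The defaults
are simulator choices tuned to reproduce the qualitative blur/SNR decay
of imaging through a ~1% Intralipid bath; they are not fitted optical
constants.  Droplet diameters follow a lognormal law with mean 4.73 µm
and SD 2.25 µm, and brightness scales with droplet volume (d^3).
Positions are sampled at the exposure midpoint; motion blur is ignored
(at <= 12 mm/s and 20 ms exposure the smear is below the PSF width in
object pixels for most of the range — a documented limitation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationView, CheckerboardSpec, board_points
from .geometry import (
    OpticsConfig,
    StereoRig,
    project_points,
    rectified_pixels,
    undistort_points,
)
from .localization import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "SceneSpec",
    "Scene",
    "FlowSpec",
    "ScatteringModel",
    "NoiseParams",
    "GroundTruth",
    "build_scene",
    "simulate_flow",
    "render_stack",
    "render_checkerboard_views",
    "render_checkerboard_image",
    "scan_poses",
    "random_board_poses",
    "certify_sparsity",
    "rendered_sigma_px",
    "sigma_z_curve",
]


@dataclass
class SceneSpec:
    """Geometry of one simulated scene.

    ``variant`` is one of static_point, tilted_tube, knot or
    vessel_network (the checkerboard z-scan is generated separately via
    :func:`scan_poses` + :func:`render_checkerboard_views`).  Tube
    dimensions default to the micro-loader tip used in the phantoms
    (137 µm I.D., 231 µm O.D.).
    """

    variant: str = "tilted_tube"
    # shared volume of interest (half-extents, mm)
    volume_halfextent_mm: tuple[float, float, float] = (10.0, 10.0, 6.0)
    # static_point
    point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # tilted_tube
    tube_inner_um: float = 137.0
    tube_outer_um: float = 231.0
    tilt_dz_dy: float = 0.3
    tube_length_mm: float = 8.0
    z0_mm: float = 1.0
    # knot
    knot_sep_um: float = 231.0
    knot_radius_mm: float = 2.0
    # vessel_network
    cap_radius_mm: float = 5.0
    n_penetrating: int = 4
    penetration_depth_um: float = 600.0


@dataclass
class Scene:
    spec: SceneSpec
    centerlines: list[np.ndarray]
    labels: list[str]


@dataclass
class FlowSpec:
    """Droplet injection: constant advection speed + Poisson arrivals.

    The diameter distribution is lognormal with the stated mean and SD
    (4.73 +/- 2.25 µm).  ``min_gap_mm`` enforces a minimum along-line
    droplet spacing (the sparse regime the matcher relies on).
    """

    speed_mm_s: float = 3.0
    rate_per_s: float = 2.0
    diameter_mean_um: float = 4.73
    diameter_sd_um: float = 2.25
    min_gap_mm: float | None = None
    # when set, each droplet rides a fixed laminar streamline offset
    # uniformly distributed over a disk of this radius around the
    # centerline (the tube lumen) instead of the centerline itself
    fill_lumen_radius_um: float | None = None

    def lognormal_params(self) -> tuple[float, float]:
        m, s = self.diameter_mean_um, self.diameter_sd_um
        sigma2 = math.log(1.0 + (s / m) ** 2)
        return math.log(m) - 0.5 * sigma2, math.sqrt(sigma2)


@dataclass
class ScatteringModel:
    """Depth-dependent PSF broadening and signal attenuation.

    sigma(z) = sigma0 * (1 + beta * depth); amplitude *= exp(-mu * depth),
    with depth measured below ``interface_z_mm`` (clipped at 0).  The
    surface PSF sigma defaults to the diffraction limit of the setup
    (~27.7 µm FWHM -> sigma = 27.7 / 2.355 µm).
    """

    sigma0_um: float = 27.7 / 2.355
    beta_per_mm: float = 0.35
    mu_per_mm: float = 0.6
    interface_z_mm: float = 0.0

    def depth(self, z_mm) -> np.ndarray:
        return np.maximum(np.asarray(z_mm, dtype=float) - self.interface_z_mm, 0.0)

    def sigma_um(self, z_mm) -> np.ndarray:
        return self.sigma0_um * (1.0 + self.beta_per_mm * self.depth(z_mm))

    def attenuation(self, z_mm) -> np.ndarray:
        return np.exp(-self.mu_per_mm * self.depth(z_mm))


@dataclass
class NoiseParams:
    """Sensor model: static background, shot noise, Gaussian read noise.

    ``photons_per_um3`` converts droplet volume to integrated signal
    counts; ``sigma_floor_px`` keeps the rendered PSF wide enough for
    well-posed Gaussian fitting on the undersampled sensor (the
    diffraction limit is smaller than one object pixel).
    """

    background: float = 100.0
    read_noise: float = 2.0
    photons_per_um3: float = 60.0
    sigma_floor_px: float = 0.8
    poisson: bool = True


@dataclass
class GroundTruth:
    """Per-frame droplet table plus acquisition metadata.

    ``df`` has columns frame, droplet_id, x, y, z (mm), diameter_um,
    intensity (integrated counts before attenuation).
    """

    df: pd.DataFrame
    n_frames: int
    frame_rate_hz: float
    labels: dict[int, str] = field(default_factory=dict)

    def frame(self, f: int) -> pd.DataFrame:
        return self.df[self.df.frame == f]

    def trajectory(self, droplet_id: int) -> pd.DataFrame:
        return self.df[self.df.droplet_id == droplet_id].sort_values("frame")


# ---------------------------------------------------------------------------
# scene geometry


def _resample_polyline(pts: np.ndarray, step_mm: float = 0.02) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step_mm)), 1)
    si = np.linspace(0.0, s[-1], n + 1)
    out = np.empty((len(si), 3))
    for c in range(3):
        out[:, c] = np.interp(si, s, pts[:, c])
    return out


def build_scene(spec: SceneSpec) -> Scene:
    """Construct the variant's centerline geometry.

    tilted_tube: a straight line with constant depth gradient dz/dy.
    knot: two circular arcs crossing above each other, centerlines
    separated axially by the tube outer diameter at the crossing.
    vessel_network: vessels on a spherical-cap cortical surface plus
    alternating descending/ascending penetrating vessels reaching the
    configured depth.  Raises if the geometry leaves the shared volume.
    """
    v = spec.variant
    if v == "static_point":
        lines = [np.asarray(spec.point_mm, dtype=float).reshape(1, 3)]
        labels = ["static"]
    elif v == "tilted_tube":
        half = spec.tube_length_mm / 2.0
        y = np.linspace(-half, half, 2)
        line = np.stack(
            [np.zeros_like(y), y, spec.z0_mm + spec.tilt_dz_dy * (y + half)], axis=1
        )
        lines = [line]
        labels = ["tube"]
    elif v == "knot":
        r = spec.knot_radius_mm
        sep = spec.knot_sep_um * 1e-3
        t = np.linspace(-0.6 * math.pi, 0.6 * math.pi, 181)
        # two arcs crossing at the origin, offset axially by the outer diameter
        arc1 = np.stack(
            [r * np.sin(t), r * (np.cos(t) - 1.0) + r * 0.0, np.full_like(t, spec.z0_mm)],
            axis=1,
        )
        arc2 = np.stack(
            [r * np.sin(t), -r * (np.cos(t) - 1.0), np.full_like(t, spec.z0_mm + sep)],
            axis=1,
        )
        # shift so both arcs pass through x=0, y=0 at t=0
        lines = [arc1, arc2]
        labels = ["knot_lower", "knot_upper"]
    elif v == "vessel_network":
        R = spec.cap_radius_mm
        lines, labels = [], []
        # surface vessels: arcs draped on the spherical cap z = R - sqrt(R^2 - x^2 - y^2)
        for k, x0 in enumerate(np.linspace(-1.5, 1.5, 3)):
            y = np.linspace(-2.0, 2.0, 81)
            x = np.full_like(y, x0)
            r2 = x * x + y * y
            z = R - np.sqrt(np.maximum(R * R - r2, 0.0))
            lines.append(np.stack([x, y, z], axis=1))
            labels.append("surface")
        # penetrating vessels: straight radial segments below the surface
        depth = spec.penetration_depth_um * 1e-3
        for k in range(spec.n_penetrating):
            ang = 2.0 * math.pi * k / spec.n_penetrating
            x0, y0 = 1.2 * math.cos(ang), 1.2 * math.sin(ang)
            z_surf = R - math.sqrt(max(R * R - x0 * x0 - y0 * y0, 0.0))
            seg = np.stack(
                [
                    np.full(2, x0),
                    np.full(2, y0),
                    np.array([z_surf, z_surf + depth]),
                ],
                axis=1,
            )
            if k % 2:  # ascending venules flow upward
                seg = seg[::-1]
            lines.append(seg)
            labels.append("descending" if k % 2 == 0 else "ascending")
    else:
        raise ValueError(f"unknown scene variant {v!r}")

    hx, hy, hz = spec.volume_halfextent_mm
    for line, lab in zip(lines, labels):
        if (
            np.any(np.abs(line[:, 0]) > hx)
            or np.any(np.abs(line[:, 1]) > hy)
            or np.any(np.abs(line[:, 2]) > hz)
        ):
            raise ValueError(f"centerline {lab!r} leaves the shared volume")
    lines = [_resample_polyline(l) if len(l) > 1 else l for l in lines]
    return Scene(spec=spec, centerlines=lines, labels=labels)


# ---------------------------------------------------------------------------
# flow simulation


def _arclength(line: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(line: np.ndarray, s_table: np.ndarray, s: float) -> np.ndarray:
    return np.array(
        [np.interp(s, s_table, line[:, c]) for c in range(3)]
    )


def simulate_flow(
    scene: Scene,
    flow: FlowSpec,
    duration_s: float,
    frame_rate_hz: float,
    seed: int = 0,
) -> GroundTruth:
    """Advect Poisson-injected droplets along the scene centerlines.

    Droplets enter each centerline as a Poisson process (the total rate
    is split evenly across centerlines), move at constant speed along
    the line and leave at its end; the line is pre-filled so flow is
    stationary from frame 0.  Positions are recorded at exposure
    midpoints.  With ``flow.speed_mm_s == 0`` (static scenes) one
    droplet per centerline persists for the whole acquisition.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    t_frames = (np.arange(n_frames) + 0.5) / frame_rate_hz
    mu_d, sd_d = flow.lognormal_params()

    records = []
    labels: dict[int, str] = {}
    droplet_id = 0
    for line, lab in zip(scene.centerlines, scene.labels):
        if flow.speed_mm_s <= 0 or len(line) == 1:
            d = float(rng.lognormal(mu_d, sd_d))
            for f in range(n_frames):
                records.append((f, droplet_id, *line[0], d, d**3))
            labels[droplet_id] = lab
            droplet_id += 1
            continue
        s_table = _arclength(line)
        length = float(s_table[-1])
        travel = length / flow.speed_mm_s
        rate = flow.rate_per_s / len(scene.centerlines)
        n_arrivals = rng.poisson(rate * (duration_s + travel))
        t0 = np.sort(rng.uniform(-travel, duration_s, size=n_arrivals))
        if flow.min_gap_mm is not None and len(t0) > 1:
            min_dt = flow.min_gap_mm / flow.speed_mm_s
            kept = [t0[0]]
            for t in t0[1:]:
                if t - kept[-1] >= min_dt:
                    kept.append(t)
            t0 = np.array(kept)
        diams = rng.lognormal(mu_d, sd_d, size=len(t0))
        for t_birth, d in zip(t0, diams):
            if flow.fill_lumen_radius_um is not None:
                rho = flow.fill_lumen_radius_um * 1e-3 * math.sqrt(rng.uniform())
                phi = rng.uniform(0.0, 2.0 * math.pi)
            active = (t_frames >= t_birth) & (
                t_frames <= t_birth + travel
            )
            for f in np.nonzero(active)[0]:
                s = flow.speed_mm_s * (t_frames[f] - t_birth)
                p = _point_at(line, s_table, s)
                if flow.fill_lumen_radius_um is not None:
                    ds = 0.01
                    ahead = _point_at(line, s_table, min(s + ds, length))
                    behind = _point_at(line, s_table, max(s - ds, 0.0))
                    tang = ahead - behind
                    tang /= max(np.linalg.norm(tang), 1e-12)
                    e1 = np.cross(tang, [0.0, 0.0, 1.0])
                    if np.linalg.norm(e1) < 1e-6:
                        e1 = np.cross(tang, [1.0, 0.0, 0.0])
                    e1 /= np.linalg.norm(e1)
                    e2 = np.cross(tang, e1)
                    p = p + rho * (math.cos(phi) * e1 + math.sin(phi) * e2)
                records.append((int(f), droplet_id, *p, float(d), float(d) ** 3))
            labels[droplet_id] = lab
            droplet_id += 1

    df = pd.DataFrame(
        records,
        columns=["frame", "droplet_id", "x", "y", "z", "diameter_um", "intensity"],
    )
    if len(df):
        df = df.sort_values(["frame", "droplet_id"]).reset_index(drop=True)
    logger.info(
        "simulated %d droplets over %d frames", len(labels), n_frames
    )
    return GroundTruth(
        df=df, n_frames=n_frames, frame_rate_hz=frame_rate_hz, labels=labels
    )


def certify_sparsity(
    truth: GroundTruth, rig: StereoRig, y_threshold_px: float
) -> bool:
    """Check that no frame holds two droplets within the matching
    threshold in rectified vertical coordinate in either view (the
    condition under which vertical-coordinate matching is identity-safe).
    """
    for f in range(truth.n_frames):
        sub = truth.frame(f)
        if len(sub) < 2:
            continue
        X = sub[["x", "y", "z"]].to_numpy()
        for cam_idx in (1, 2):
            cam = rig.camera(cam_idx)
            uv = project_points(X, cam.intrinsics, cam.extrinsics)
            rect = rectified_pixels(
                undistort_points(uv, cam.intrinsics), rig, cam_idx
            )
            v = np.sort(rect[:, 1])
            if np.any(np.diff(v) < y_threshold_px):
                return False
    return True


# ---------------------------------------------------------------------------
# image rendering


def _draw_gaussian(
    img: np.ndarray, u: float, v: float, sigma: float, total: float
) -> None:
    h, w = img.shape
    r = int(math.ceil(4.0 * sigma))
    u0, v0 = int(round(u)), int(round(v))
    ulo, uhi = max(u0 - r, 0), min(u0 + r + 1, w)
    vlo, vhi = max(v0 - r, 0), min(v0 + r + 1, h)
    if ulo >= uhi or vlo >= vhi:
        return
    uu = np.arange(ulo, uhi)
    vv = np.arange(vlo, vhi)
    gu = np.exp(-((uu - u) ** 2) / (2 * sigma * sigma))
    gv = np.exp(-((vv - v) ** 2) / (2 * sigma * sigma))
    img[vlo:vhi, ulo:uhi] += (total / (2 * math.pi * sigma * sigma)) * np.outer(
        gv, gu
    )


def rendered_sigma_px(
    scattering: ScatteringModel,
    optics: OpticsConfig,
    z_mm,
    sigma_floor_px: float = 0.8,
) -> np.ndarray:
    """Pixel-domain spot sigma at depth z.

    The scattering-broadened object-plane sigma is combined in
    quadrature with a fixed system floor (pixelation / residual
    aberrations), keeping the rendered spot wide enough for well-posed
    Gaussian fitting on the undersampled sensor while remaining
    strictly increasing with depth.
    """
    s_px = scattering.sigma_um(np.asarray(z_mm, dtype=float)) / optics.object_pixel_um
    return np.sqrt(s_px * s_px + sigma_floor_px * sigma_floor_px)


def render_stack(
    truth: GroundTruth,
    rig: StereoRig,
    optics: OpticsConfig | None = None,
    scattering: ScatteringModel | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack]:
    """Render the two cameras' image stacks for a simulated flow.

    Each droplet is projected through the full camera model (distortion
    included) and drawn as a 2D Gaussian whose object-plane sigma follows
    the scattering model (converted to pixels, floored for samplability)
    and whose integrated signal scales with droplet volume times the
    depth attenuation.  Static background is added, then Poisson shot
    noise and Gaussian read noise; 16-bit clipping.  Warns when more
    than 10% of pixels saturate.
    """
    optics = optics or OpticsConfig()
    scattering = scattering or ScatteringModel()
    noise = noise or NoiseParams()
    h, w = optics.sensor_height, optics.sensor_width
    child = np.random.SeedSequence(seed).spawn(2)
    stacks = []
    for cam_idx, ss in zip((1, 2), child):
        rng = np.random.default_rng(ss)
        cam = rig.camera(cam_idx)
        frames = np.empty((truth.n_frames, h, w), dtype=np.uint16)
        for f in range(truth.n_frames):
            img = np.full((h, w), float(noise.background))
            sub = truth.frame(f)
            if len(sub):
                X = sub[["x", "y", "z"]].to_numpy()
                uv = project_points(X, cam.intrinsics, cam.extrinsics)
                sig_px = rendered_sigma_px(
                    scattering, optics, X[:, 2], noise.sigma_floor_px
                )
                totals = (
                    noise.photons_per_um3
                    * (math.pi / 6.0)
                    * sub["diameter_um"].to_numpy() ** 3
                    * scattering.attenuation(X[:, 2])
                )
                for (u, v), s, tot in zip(uv, sig_px, totals):
                    _draw_gaussian(img, u, v, float(s), float(tot))
            if noise.poisson:
                img = rng.poisson(img).astype(float)
            if noise.read_noise > 0:
                img = img + rng.normal(0.0, noise.read_noise, size=img.shape)
            np.clip(img, 0, 65535, out=img)
            frames[f] = img.astype(np.uint16)
        sat = float(np.mean(frames == 65535))
        if sat > 0.10:
            logger.warning("camera %d: %.1f%% of pixels saturated", cam_idx, 100 * sat)
        stacks.append(
            ImageStack(frames, frame_rate_hz=truth.frame_rate_hz, camera_id=cam_idx)
        )
    return stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# checkerboard rendering (calibration + z-scan inputs)


def scan_poses(
    n_layers: int,
    step_um: float,
    z_start_mm: float = -1.5,
    spec: CheckerboardSpec | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fronto-parallel board poses translated axially in fixed steps.

    Mimics the motorized z-scan characterization: ``n_layers`` planes
    spaced ``step_um`` apart starting at ``z_start_mm``.  When a board
    spec is given the grid is centered laterally on the optical axis.
    Poses map board coordinates to world coordinates.
    """
    offset = np.zeros(3)
    if spec is not None:
        offset[:2] = -board_points(spec).mean(axis=0)[:2]
    poses = []
    for i in range(n_layers):
        t = offset + [0.0, 0.0, z_start_mm + i * step_um * 1e-3]
        poses.append((np.eye(3), t))
    return poses


def _board_in_view(
    Xw: np.ndarray, rig: StereoRig, margin_px: float = 2.0
) -> bool:
    w = 2 * rig.cam1.intrinsics.cx + 1
    h = 2 * rig.cam1.intrinsics.cy + 1
    for cam_idx in (1, 2):
        cam = rig.camera(cam_idx)
        try:
            uv = project_points(Xw, cam.intrinsics, cam.extrinsics)
        except ValueError:
            return False
        if (
            uv[:, 0].min() < margin_px
            or uv[:, 1].min() < margin_px
            or uv[:, 0].max() > w - 1 - margin_px
            or uv[:, 1].max() > h - 1 - margin_px
        ):
            return False
    return True


def random_board_poses(
    n: int,
    rng: np.random.Generator,
    spec: CheckerboardSpec,
    rig: StereoRig | None = None,
    tilt_scale: float = 0.35,
    center_scale_mm: float = 2.0,
    z_scale_mm: float = 1.0,
    max_tries: int = 200,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random board poses spanning distinct positions and orientations.

    When a rig is given, poses are rejection-sampled until the full
    board stays inside both sensors.
    """
    from scipy.spatial.transform import Rotation

    obj = board_points(spec)
    extent = obj.mean(axis=0)
    poses = []
    for _ in range(n):
        for _try in range(max_tries):
            R = Rotation.from_rotvec(rng.normal(scale=tilt_scale, size=3)).as_matrix()
            c = rng.normal(scale=1.0, size=3) * [
                center_scale_mm,
                center_scale_mm,
                z_scale_mm,
            ]
            t = c - R @ extent  # board centered near c
            if rig is None or _board_in_view(obj @ R.T + t, rig):
                poses.append((R, t))
                break
        else:
            raise RuntimeError("could not sample an in-view board pose")
    return poses


def render_checkerboard_views(
    spec: CheckerboardSpec,
    poses: list[tuple[np.ndarray, np.ndarray]],
    rig: StereoRig,
    corner_noise_px: float = 0.0,
    seed: int = 0,
) -> list[CalibrationView]:
    """Analytic corner projections through the full distortion model.

    Gaussian pixel noise of the given sigma is added independently per
    corner and camera.  Raises (naming the pose) if any corner leaves
    either sensor.
    """
    rng = np.random.default_rng(seed)
    obj = board_points(spec)
    views = []
    w = 2 * rig.cam1.intrinsics.cx + 1  # sensor bounds from principal point
    h = 2 * rig.cam1.intrinsics.cy + 1
    for i, (R, t) in enumerate(poses):
        Xw = obj @ R.T + t
        corners = []
        for cam_idx in (1, 2):
            cam = rig.camera(cam_idx)
            uv = project_points(Xw, cam.intrinsics, cam.extrinsics)
            if (
                uv[:, 0].min() < 0
                or uv[:, 1].min() < 0
                or uv[:, 0].max() > w - 1
                or uv[:, 1].max() > h - 1
            ):
                raise ValueError(f"pose {i}: board leaves camera {cam_idx} view")
            if corner_noise_px > 0:
                uv = uv + rng.normal(scale=corner_noise_px, size=uv.shape)
            corners.append(uv)
        views.append(CalibrationView(corners[0], corners[1], view_id=i))
    return views


def render_checkerboard_image(
    spec: CheckerboardSpec,
    H: np.ndarray,
    shape: tuple[int, int],
    supersample: int = 8,
    blur_px: float = 1.2,
    contrast: tuple[float, float] = (50.0, 200.0),
) -> np.ndarray:
    """Rasterize a bright-field checkerboard through a plane homography.

    ``H`` maps board-plane mm coordinates to pixels (distortion-free).
    Rendered with sub-pixel supersampling (processed in row chunks to
    bound memory) and Gaussian blur so corner detection can be
    validated against the analytic projections.
    """
    from scipy import ndimage

    h, w = shape
    s = supersample
    Hinv = np.linalg.inv(H)
    sq = spec.square_size_mm
    lo, hi = contrast
    img = np.empty((h, w))
    chunk = max(1, 2048 // (w * s // 1024 + 1))
    for r0 in range(0, h, chunk):
        r1 = min(r0 + chunk, h)
        vv, uu = np.mgrid[r0 * s : r1 * s, 0 : w * s]
        u = (uu + 0.5) / s - 0.5
        v = (vv + 0.5) / s - 0.5
        den = Hinv[2, 0] * u + Hinv[2, 1] * v + Hinv[2, 2]
        bx = (Hinv[0, 0] * u + Hinv[0, 1] * v + Hinv[0, 2]) / den
        by = (Hinv[1, 0] * u + Hinv[1, 1] * v + Hinv[1, 2]) / den
        # squares extend one ring beyond the inner-corner grid
        inside = (
            (bx >= -sq)
            & (bx <= spec.inner_cols * sq)
            & (by >= -sq)
            & (by <= spec.inner_rows * sq)
        )
        parity = (np.floor(bx / sq) + np.floor(by / sq)).astype(int) % 2
        block = np.where(inside, np.where(parity == 0, lo, hi), 0.5 * (lo + hi))
        img[r0:r1] = block.reshape(r1 - r0, s, w, s).mean(axis=(1, 3))
    return ndimage.gaussian_filter(img, blur_px)


def sigma_z_curve(
    scattering: ScatteringModel,
    optics: OpticsConfig,
    z_mm: np.ndarray,
    sigma_floor_px: float = 0.8,
) -> np.ndarray:
    """Rendered spot sigma (px) versus depth: the diffusion-depth table."""
    return rendered_sigma_px(scattering, optics, z_mm, sigma_floor_px)
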