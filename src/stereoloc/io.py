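"""Readers and writers for the pipeline's file formats.

Image stacks and volumes are multi-page TIFF (frame order = time for
stacks, z-pages for volumes, with a plain-text sidecar header carrying
origin and voxel size).  Tables (spots, pairs, points, tracks, corners)
are CSV with '#'-prefixed header comments recording the config hash and
seed.  The stereo rig is a flat key-value text file.  All lengths in
file interfaces are mm unless the column name carries a unit suffix
(_um, _px).  Pixels are 0-based with centers on integer coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationView
from .geometry import (
    Camera,
    CameraExtrinsics,
    CameraIntrinsics,
    StereoRig,
    rectify_rig,
)
from .localization import ImageStack, LocalizedSpot
from .matching import MatchedPair, WorldPoint
from .rendering import VoxelGrid
from .tracking import Track

__all__ = [
    "write_rig",
    "read_rig",
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "spots_to_frame",
    "frame_to_spots",
    "write_table",
    "read_table",
    "pairs_to_frame",
    "points_to_frame",
    "frame_to_points",
    "tracks_to_frame",
    "corners_to_frame",
    "frame_to_views",
]


# ---------------------------------------------------------------------------
# rig file


def write_rig(rig: StereoRig, path: str | Path) -> None:
    lines = [f"theta = {float(rig.theta_deg)!r}"]
    for idx in (1, 2):
        cam = rig.camera(idx)
        i = cam.intrinsics
        for k in ("fx", "fy", "cx", "cy", "k1", "k2"):
            lines.append(f"cam{idx}.{k} = {float(getattr(i, k))!r}")
        R = " ".join(repr(float(v)) for v in cam.extrinsics.R.ravel())
        t = " ".join(repr(float(v)) for v in cam.extrinsics.t)
        lines.append(f"cam{idx}.R = {R}")
        lines.append(f"cam{idx}.t = {t}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rig(path: str | Path) -> StereoRig:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    cams = []
    for idx in (1, 2):
        intr = CameraIntrinsics(
            *(float(kv[f"cam{idx}.{k}"]) for k in ("fx", "fy", "cx", "cy", "k1", "k2"))
        )
        R = np.array([float(x) for x in kv[f"cam{idx}.R"].split()]).reshape(3, 3)
        t = np.array([float(x) for x in kv[f"cam{idx}.t"].split()])
        cams.append(Camera(intr, CameraExtrinsics(R, t)))
    rig = StereoRig(cam1=cams[0], cam2=cams[1], theta_deg=float(kv["theta"]))
    return rectify_rig(rig)


# ---------------------------------------------------------------------------
# TIFF stacks and volumes


def write_stack(stack: ImageStack, path: str | Path) -> None:
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(frames, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    exposure_ms: float | None = None,
    transfer_gap_ms: float | None = None,
    camera_id: int = 1,
) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, frame_rate_hz, exposure_ms, transfer_gap_ms, camera_id)


def write_volume(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Volume as z-page TIFF plus a sidecar text header."""
    pages = np.moveaxis(np.asarray(volume, dtype=np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = Path(str(path) + ".hdr")
    ox, oy, oz = (float(v) for v in grid.origin)
    sidecar.write_text(
        f"origin_mm = {ox!r} {oy!r} {oz!r}\n"
        f"voxel_size_um = {float(grid.voxel_size_um)!r}\n"
        f"dims = {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n"
        "page_axis = z\n"
    )


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    pages = tifffile.imread(path)
    volume = np.moveaxis(pages, 0, 2)
    kv = {}
    for line in Path(str(path) + ".hdr").read_text().splitlines():
        if "=" in line:
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    origin = np.array([float(x) for x in kv["origin_mm"].split()])
    return volume, origin, float(kv["voxel_size_um"])


# ---------------------------------------------------------------------------
# CSV tables


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    """CSV with '#' header comments carrying provenance."""
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash = {config_hash}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def spots_to_frame(spots_per_frame: list[list[LocalizedSpot]]) -> pd.DataFrame:
    rows = [
        (s.camera_id, s.frame, s.u, s.v, s.amplitude, s.background, s.sigma_px,
         s.residual)
        for frame_spots in spots_per_frame
        for s in frame_spots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "camera_id", "frame", "u_px", "v_px", "amplitude", "background",
            "sigma_px", "residual",
        ],
    )


def frame_to_spots(df: pd.DataFrame, n_frames: int | None = None
                   ) -> list[list[LocalizedSpot]]:
    n = int(n_frames if n_frames is not None else (df.frame.max() + 1 if len(df) else 0))
    out: list[list[LocalizedSpot]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            LocalizedSpot(
                frame=int(row.frame),
                u=float(row.u_px),
                v=float(row.v_px),
                amplitude=float(row.amplitude),
                background=float(row.background),
                sigma_px=float(row.sigma_px),
                residual=float(row.residual),
                camera_id=int(row.camera_id),
            )
        )
    return out


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    rows = [
        (p.frame, p.spot1.u, p.spot1.v, p.spot2.u, p.spot2.v, p.dy_rect_px,
         p.disparity_px)
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["frame", "u1_px", "v1_px", "u2_px", "v2_px", "dy_rect_px",
                 "disparity_px"],
    )


def points_to_frame(points: list[WorldPoint]) -> pd.DataFrame:
    rows = [(p.frame, p.x, p.y, p.z, p.ray_gap_mm) for p in points]
    return pd.DataFrame(rows, columns=["frame", "x_mm", "y_mm", "z_mm", "ray_gap_mm"])


def frame_to_points(df: pd.DataFrame) -> list[list[WorldPoint]]:
    n = int(df.frame.max() + 1) if len(df) else 0
    out: list[list[WorldPoint]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            WorldPoint(
                frame=int(row.frame),
                x=float(row.x_mm),
                y=float(row.y_mm),
                z=float(row.z_mm),
                ray_gap_mm=float(row.ray_gap_mm),
            )
        )
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tid, track in enumerate(tracks):
        v = track.velocities
        for i, (f, p) in enumerate(zip(track.frames, track.points)):
            if v is not None and i < len(v):
                vx, vy, vz = v[i]
            else:
                vx = vy = vz = np.nan
            rows.append((tid, f, p[0], p[1], p[2], vx, vy, vz))
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x_mm", "y_mm", "z_mm",
                 "vx_mm_s", "vy_mm_s", "vz_mm_s"],
    )


def corners_to_frame(views: list[CalibrationView]) -> pd.DataFrame:
    rows = []
    for v in views:
        for cam_id, corners in ((1, v.corners1), (2, v.corners2)):
            if corners is None:
                continue
            for i, (u, vv) in enumerate(np.asarray(corners)):
                rows.append((v.view_id, cam_id, i, u, vv))
    return pd.DataFrame(
        rows, columns=["view_id", "camera_id", "corner_index", "u_px", "v_px"]
    )


def frame_to_views(df: pd.DataFrame) -> list[CalibrationView]:
    views = []
    for vid, sub in df.groupby("view_id"):
        corners = {}
        for cam_id, csub in sub.groupby("camera_id"):
            csub = csub.sort_values("corner_index")
            corners[cam_id] = csub[["u_px", "v_px"]].to_numpy()
        views.append(
            CalibrationView(
                corners1=corners.get(1),
                corners2=corners.get(2),
                view_id=int(vid),
            )
        )
    return views
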