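"""Pair localized spots across the two rectified views and triangulate.

Because flowing droplets are spatio-temporally sparse, correspondence
reduces to comparing rectified vertical coordinates: a pair is accepted
only when each spot is the *unique* candidate of the other within a
vertical threshold.  Any spot with two or more candidates is ambiguous
(most likely several droplets in close proximity) and all its candidate
pairings are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    MediumConfig,
    StereoRig,
    correct_refraction,
    rectified_pixels,
    triangulate,
    undistort_points,
)
from .localization import LocalizedSpot

logger = logging.getLogger(__name__)

__all__ = [
    "MatchConfig",
    "MatchedPair",
    "WorldPoint",
    "match_frame",
    "match_stack",
    "pairs_to_points",
]


@dataclass(frozen=True)
class MatchConfig:
    """Vertical-coordinate matching threshold (rectified px).

    ``y_threshold_px`` is ~3x the expected rectification residual under
    typical localization noise.  ``require_reciprocal_unique`` enforces
    uniqueness in both directions (the ambiguity-exclusion rule).
    Optional disparity bounds crop the volume of interest.
    """

    y_threshold_px: float = 1.0
    require_reciprocal_unique: bool = True
    min_disparity_px: float | None = None
    max_disparity_px: float | None = None

    def __post_init__(self) -> None:
        if self.y_threshold_px <= 0:
            raise ValueError("y_threshold must be positive")


@dataclass(frozen=True)
class MatchedPair:
    frame: int
    spot1: LocalizedSpot
    spot2: LocalizedSpot
    rect1: tuple[float, float]
    rect2: tuple[float, float]
    dy_rect_px: float
    disparity_px: float


@dataclass(frozen=True)
class WorldPoint:
    """One triangulated droplet position (mm, world frame)."""

    frame: int
    x: float
    y: float
    z: float
    ray_gap_mm: float
    refraction_corrected: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _rectify_spots(
    spots: list[LocalizedSpot], rig: StereoRig, camera: int
) -> np.ndarray:
    if not spots:
        return np.empty((0, 2))
    pix = np.array([[s.u, s.v] for s in spots])
    norm = undistort_points(pix, rig.camera(camera).intrinsics)
    return rectified_pixels(norm, rig, camera)


def match_frame(
    spots1: list[LocalizedSpot],
    spots2: list[LocalizedSpot],
    rig: StereoRig,
    cfg: MatchConfig | None = None,
) -> list[MatchedPair]:
    """Match one frame's spots across the two views.

    A pair (i, j) is accepted iff j is the unique camera-2 candidate
    within ``y_threshold`` of spot i *and* vice versa; spots with
    multiple candidates void all their pairings.  Deterministic; empty
    inputs give an empty list.
    """
    cfg = cfg or MatchConfig()
    if not spots1 or not spots2:
        return []
    r1 = _rectify_spots(spots1, rig, 1)
    r2 = _rectify_spots(spots2, rig, 2)
    dy = r1[:, 1][:, None] - r2[:, 1][None, :]
    cand = np.abs(dy) < cfg.y_threshold_px
    if cfg.min_disparity_px is not None or cfg.max_disparity_px is not None:
        disp = r1[:, 0][:, None] - r2[:, 0][None, :]
        if cfg.min_disparity_px is not None:
            cand &= disp >= cfg.min_disparity_px
        if cfg.max_disparity_px is not None:
            cand &= disp <= cfg.max_disparity_px

    n1 = cand.sum(axis=1)
    n2 = cand.sum(axis=0)
    pairs = []
    for i, j in zip(*np.nonzero(cand)):
        if cfg.require_reciprocal_unique and (n1[i] != 1 or n2[j] != 1):
            continue
        if not cfg.require_reciprocal_unique and n1[i] != 1:
            continue
        pairs.append(
            MatchedPair(
                frame=spots1[i].frame,
                spot1=spots1[i],
                spot2=spots2[j],
                rect1=(float(r1[i, 0]), float(r1[i, 1])),
                rect2=(float(r2[j, 0]), float(r2[j, 1])),
                dy_rect_px=float(dy[i, j]),
                disparity_px=float(r1[i, 0] - r2[j, 0]),
            )
        )
    return pairs


def match_stack(
    spots1_per_frame: list[list[LocalizedSpot]],
    spots2_per_frame: list[list[LocalizedSpot]],
    rig: StereoRig,
    cfg: MatchConfig | None = None,
) -> tuple[list[MatchedPair], float]:
    """Frame-wise matching over synchronized stacks.

    Returns all accepted pairs and the match rate
    ``n_pairs / sum_t min(n_spots1, n_spots2)``.
    """
    if len(spots1_per_frame) != len(spots2_per_frame):
        raise ValueError(
            f"frame-count mismatch between cameras: "
            f"{len(spots1_per_frame)} vs {len(spots2_per_frame)}"
        )
    pairs: list[MatchedPair] = []
    possible = 0
    for s1, s2 in zip(spots1_per_frame, spots2_per_frame):
        possible += min(len(s1), len(s2))
        pairs.extend(match_frame(s1, s2, rig, cfg))
    rate = len(pairs) / possible if possible else 0.0
    logger.info("matched %d pairs (rate %.3f)", len(pairs), rate)
    return pairs, rate


def pairs_to_points(
    pairs: list[MatchedPair],
    rig: StereoRig,
    medium: MediumConfig | None = None,
    voi_bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[WorldPoint]:
    """Triangulate matched pairs into world points.

    Undistorts each spot, triangulates by the ray-midpoint method, and
    optionally applies the refractive depth rescale and a volume-of-
    interest crop (dropped points are counted in the log).
    """
    if not pairs:
        return []
    p1 = undistort_points(
        np.array([[p.spot1.u, p.spot1.v] for p in pairs]), rig.cam1.intrinsics
    )
    p2 = undistort_points(
        np.array([[p.spot2.u, p.spot2.v] for p in pairs]), rig.cam2.intrinsics
    )
    pts, gaps = triangulate(p1, p2, rig)
    corrected = False
    if medium is not None:
        pts = correct_refraction(pts, medium)
        corrected = True
    keep = np.ones(len(pts), dtype=bool)
    if voi_bounds is not None:
        lo, hi = voi_bounds
        keep = np.all(pts >= lo, axis=1) & np.all(pts <= hi, axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d points outside the volume of interest", dropped)
    return [
        WorldPoint(
            frame=pair.frame,
            x=float(p[0]),
            y=float(p[1]),
            z=float(p[2]),
            ray_gap_mm=float(g),
            refraction_corrected=corrected,
        )
        for pair, p, g, k in zip(pairs, pts, gaps, keep)
        if k
    ]
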