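"""Link triangulated droplet positions over time and compute velocities.

Frame-to-frame linking is an optimal one-to-one assignment: among all
candidate links with displacement at most the max-linking-distance
(MLD), the matching minimizing the total squared distance (with an
MLD^2/2 cost per unlinked endpoint) is chosen via the Hungarian
algorithm.  In sparse scenes this reduces to nearest-neighbor linking;
on crossings it is strictly better and deterministic.

Velocities follow from finite differences scaled by the frame rate:
``v = (delta position) * frame_rate``, with lateral speed
``sqrt(vx^2 + vy^2)``, axial velocity ``vz`` (signed: the ascending /
descending discriminator) and total speed ``|v|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .matching import WorldPoint

logger = logging.getLogger(__name__)

__all__ = [
    "TrackingConfig",
    "Track",
    "link_tracks",
    "filter_tracks",
    "track_velocities",
    "max_trackable_speed",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Linking parameters.

    ``mld_um`` is the maximum displacement of one droplet between
    consecutive frames; with the frame rate it bounds the measurable
    speed (300 µm at 40 Hz -> 12 mm/s).  ``min_track_length`` removes
    short fragments (false connections, stacked droplets).
    """

    mld_um: float = 300.0
    min_track_length: int = 5
    gap_closing: int = 0

    def __post_init__(self) -> None:
        if self.mld_um <= 0:
            raise ValueError("MLD must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.gap_closing < 0:
            raise ValueError("gap_closing must be >= 0")


@dataclass
class Track:
    """Ordered 3D trajectory of one droplet.

    ``frames`` are strictly increasing; ``points`` is (N, 3) mm.
    ``velocities`` (per-step, mm/s) is filled by
    :func:`track_velocities`.
    """

    frames: list[int] = field(default_factory=list)
    points: list[np.ndarray] = field(default_factory=list)
    world_points: list[WorldPoint] = field(default_factory=list)
    velocities: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.points).reshape(-1, 3)


def frame_assignment(
    prev: np.ndarray, curr: np.ndarray, mld_mm: float
) -> list[tuple[int, int]]:
    """Optimal gated one-to-one links between two frames' point sets.

    Minimizes the summed squared link distances plus ``mld^2 / 2`` per
    unlinked point, over matchings whose links all satisfy d <= MLD.
    Implemented as a Hungarian assignment on the standard augmented
    (n1+n2) square cost matrix.  Ties resolve deterministically (lowest
    point index, via the solver's deterministic scan order).
    """
    n1, n2 = len(prev), len(curr)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    gate = d2 <= mld_mm * mld_mm
    if not gate.any():
        return []
    alt = 0.5 * mld_mm * mld_mm * (1.0 + 1e-9)
    big = 1e6 * max(alt, 1.0)
    C = np.full((n1 + n2, n1 + n2), big)
    C[:n1, :n2] = np.where(gate, d2, big)
    C[:n1, n2:] = big
    C[n1:, :n2] = big
    np.fill_diagonal(C[:n1, n2:], alt)
    np.fill_diagonal(C[n1:, :n2], alt)
    C[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(C)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n1 and j < n2 and gate[i, j]
    ]


def link_tracks(
    points_by_frame: list[list[WorldPoint]], cfg: TrackingConfig | None = None
) -> list[Track]:
    """Link per-frame world points into trajectories.

    Consecutive frames are joined by :func:`frame_assignment`; points
    without a link start new tracks.  With ``gap_closing`` g > 0, a
    track that missed up to g frames remains eligible for linking.
    Deterministic.
    """
    cfg = cfg or TrackingConfig()
    mld_mm = cfg.mld_um * 1e-3
    tracks: list[Track] = []
    active: list[Track] = []
    for f, pts in enumerate(points_by_frame):
        coords = np.array([p.xyz for p in pts]).reshape(-1, 3)
        # tracks still eligible for extension
        eligible = [t for t in active if f - t.frames[-1] <= cfg.gap_closing + 1]
        tails = np.array([t.points[-1] for t in eligible]).reshape(-1, 3)
        links = frame_assignment(tails, coords, mld_mm) if len(eligible) else []
        linked_curr = set()
        for i, j in links:
            t = eligible[i]
            t.frames.append(f)
            t.points.append(coords[j])
            t.world_points.append(pts[j])
            linked_curr.add(j)
        still_active = [t for t in eligible if t.frames[-1] == f]
        waiting = [
            t
            for t in active
            if t.frames[-1] != f and f - t.frames[-1] <= cfg.gap_closing
        ]
        for j, p in enumerate(pts):
            if j not in linked_curr:
                t = Track(frames=[f], points=[coords[j]], world_points=[p])
                tracks.append(t)
                still_active.append(t)
        active = still_active + waiting
    logger.info("linked %d tracks from %d frames", len(tracks), len(points_by_frame))
    return tracks


def filter_tracks(tracks: list[Track], cfg: TrackingConfig | None = None) -> list[Track]:
    """Drop tracks shorter than ``min_track_length`` frames."""
    cfg = cfg or TrackingConfig()
    kept = [t for t in tracks if len(t) >= cfg.min_track_length]
    logger.info(
        "removed %d / %d tracks shorter than %d frames",
        len(tracks) - len(kept),
        len(tracks),
        cfg.min_track_length,
    )
    return kept


def track_velocities(
    track: Track, frame_rate_hz: float
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-step velocity vectors (mm/s) and per-track summaries.

    Each step velocity is the 3D displacement divided by the elapsed
    frame time.  Summaries report the per-track means of lateral speed,
    signed axial velocity and total speed.  Single-point tracks yield an
    empty velocity array.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    xyz = track.xyz
    if len(xyz) < 2:
        track.velocities = np.empty((0, 3))
        return track.velocities, {
            "mean_lateral_mm_s": np.nan,
            "mean_axial_mm_s": np.nan,
            "mean_speed_mm_s": np.nan,
        }
    dframes = np.diff(np.asarray(track.frames, dtype=float))
    v = np.diff(xyz, axis=0) * (frame_rate_hz / dframes[:, None])
    lateral = np.hypot(v[:, 0], v[:, 1])
    speed = np.linalg.norm(v, axis=1)
    track.velocities = v
    summary = {
        "mean_lateral_mm_s": float(lateral.mean()),
        "mean_axial_mm_s": float(v[:, 2].mean()),
        "mean_speed_mm_s": float(speed.mean()),
    }
    return v, summary


def max_trackable_speed(cfg: TrackingConfig, frame_rate_hz: float) -> float:
    """Fastest measurable flow: MLD x frame rate, in mm/s."""
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    return cfg.mld_um * 1e-3 * frame_rate_hz
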