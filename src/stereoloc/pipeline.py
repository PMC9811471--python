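"""End-to-end orchestration of the reconstruction workflow.

localize both stacks -> match pairs across views -> triangulate ->
link / filter / velocities -> compound into a voxel grid with velocity
maps.  Each stage's counts are logged; any stage failure aborts with a
stage-named error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, derived_constants
from .geometry import StereoRig
from .localization import ImageStack, LocalizedSpot, localize_stack
from .matching import MatchedPair, WorldPoint, match_stack, pairs_to_points
from .rendering import VoxelGrid, rasterize_tracks, velocity_volume
from .tracking import Track, filter_tracks, link_tracks, track_velocities

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    spots1: list[list[LocalizedSpot]]
    spots2: list[list[LocalizedSpot]]
    pairs: list[MatchedPair]
    match_rate: float
    points: list[WorldPoint]
    tracks: list[Track]
    grid: VoxelGrid | None
    track_summaries: list[dict] = field(default_factory=list)
    constants: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig,
    stack1: ImageStack,
    stack2: ImageStack,
    rig: StereoRig,
    grid_bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> PipelineResult:
    """Run the full reconstruction on a synchronized stack pair.

    ``grid_bounds`` (lo, hi in mm) sets the compounding volume; when
    None it is fitted to the triangulated points.  Empty stacks produce
    empty tables and no volume (with a warning).
    """
    if stack1.n_frames != stack2.n_frames:
        raise PipelineStageError(
            f"stage 'input' failed: frame-count mismatch "
            f"({stack1.n_frames} vs {stack2.n_frames})"
        )
    consts = derived_constants(config)
    frame_rate = (
        stack1.frame_rate_hz
        if stack1.frame_rate_hz is not None
        else consts["frame_rate_hz"]
    )

    spots1 = _stage("localization")(localize_stack, stack1, config.localization)
    spots2 = _stage("localization")(localize_stack, stack2, config.localization)
    logger.info(
        "localization: %d + %d spots",
        sum(map(len, spots1)),
        sum(map(len, spots2)),
    )

    pairs, rate = _stage("matching")(match_stack, spots1, spots2, rig, config.matching)
    points = _stage("triangulation")(pairs_to_points, pairs, rig, config.medium)
    logger.info("triangulation: %d points", len(points))

    points_by_frame: list[list[WorldPoint]] = [[] for _ in range(stack1.n_frames)]
    for p in points:
        points_by_frame[p.frame].append(p)
    tracks = _stage("tracking")(link_tracks, points_by_frame, config.tracking)
    tracks = _stage("tracking")(filter_tracks, tracks, config.tracking)
    summaries = []
    for t in tracks:
        _, summary = track_velocities(t, frame_rate)
        summaries.append(summary)
    logger.info("tracking: %d tracks kept", len(tracks))

    grid = None
    if tracks:
        if grid_bounds is None:
            allp = np.concatenate([t.xyz for t in tracks])
            margin = 0.05
            lo = allp.min(axis=0) - margin
            hi = allp.max(axis=0) + margin
        else:
            lo, hi = grid_bounds
        grid = VoxelGrid.from_bounds(lo, hi, config.grid.voxel_size_um)
        _stage("rendering")(rasterize_tracks, tracks, grid)
        _stage("rendering")(velocity_volume, tracks, grid)
    else:
        logger.warning("no tracks survived filtering; volume not rendered")

    return PipelineResult(
        spots1=spots1,
        spots2=spots2,
        pairs=pairs,
        match_rate=rate,
        points=points,
        tracks=tracks,
        grid=grid,
        track_summaries=summaries,
        constants=consts,
    )
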