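"""Pipeline configuration: a strict flat key-value format.

The on-disk format is diffable and hashable plain text::

    acquisition.frame_rate_hz = 40
    optics.magnification = 0.37
    tracking.mld_um = 300

Unknown keys are rejected; cross-field identities (frame rate versus
exposure + transfer gap) are checked at load.  Defaults mirror the
in vivo acquisition: 20 ms exposure + 5 ms transfer at 40 Hz, 15 µm
pixel pitch at x0.37 magnification, +/-20 degree vergence, 300 µm MLD.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .geometry import MediumConfig, OpticsConfig
from .localization import LocalizationParams
from .matching import MatchConfig
from .tracking import TrackingConfig

__all__ = [
    "AcquisitionConfig",
    "PipelineConfig",
    "derived_constants",
    "load_config",
    "dump_config",
    "config_hash",
]


@dataclass
class AcquisitionConfig:
    frame_rate_hz: float = 40.0
    exposure_ms: float = 20.0
    transfer_gap_ms: float = 5.0

    def __post_init__(self) -> None:
        implied = 1000.0 / (self.exposure_ms + self.transfer_gap_ms)
        if abs(self.frame_rate_hz - implied) > 1e-6 * implied:
            raise ValueError(
                f"frame_rate_hz={self.frame_rate_hz} inconsistent with "
                f"1000/(exposure+transfer_gap)={implied:.6g}"
            )


@dataclass
class GridConfig:
    voxel_size_um: float = 10.0


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    theta_deg: float = 20.0
    medium: MediumConfig | None = None
    localization: LocalizationParams = field(default_factory=LocalizationParams)
    matching: MatchConfig = field(default_factory=MatchConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 0


def derived_constants(cfg: PipelineConfig) -> dict[str, float]:
    """Quantities implied by the configuration.

    object_pixel_um = pixel pitch / magnification; frame rate from the
    exposure/transfer timing; the maximum trackable speed from the MLD
    and frame rate.
    """
    acq = cfg.acquisition
    frame_rate = 1000.0 / (acq.exposure_ms + acq.transfer_gap_ms)
    return {
        "object_pixel_um": cfg.optics.object_pixel_um,
        "frame_rate_hz": frame_rate,
        "frame_period_ms": 1000.0 / frame_rate,
        "max_trackable_speed_mm_s": cfg.tracking.mld_um * 1e-3 * frame_rate,
    }


# ---------------------------------------------------------------------------
# flat key-value (de)serialization

_SECTIONS = {
    "acquisition": (
        "acquisition",
        AcquisitionConfig,
        ["frame_rate_hz", "exposure_ms", "transfer_gap_ms"],
    ),
    "optics": (
        "optics",
        OpticsConfig,
        ["magnification", "pixel_pitch_um", "sensor_width", "sensor_height"],
    ),
    "medium": ("medium", MediumConfig, ["refractive_index", "interface_z"]),
    "localization": (
        "localization",
        LocalizationParams,
        ["wavelet_level", "k_sigma", "window_radius_px"],
    ),
    "matching": (
        "matching",
        MatchConfig,
        ["y_threshold_px", "min_disparity_px", "max_disparity_px"],
    ),
    "tracking": (
        "tracking",
        TrackingConfig,
        ["mld_um", "min_track_length", "gap_closing"],
    ),
    "grid": ("grid", GridConfig, ["voxel_size_um"]),
}

_INT_KEYS = {
    "sensor_width",
    "sensor_height",
    "wavelet_level",
    "window_radius_px",
    "min_track_length",
    "gap_closing",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse the flat key-value config file; unknown keys are errors."""
    raw: dict[str, dict[str, float]] = {}
    top: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if "." in key:
            section, name = key.split(".", 1)
            if section not in _SECTIONS:
                raise ValueError(f"{path}:{lineno}: unknown section {section!r}")
            _, _, allowed = _SECTIONS[section]
            if name not in allowed:
                raise ValueError(
                    f"{path}:{lineno}: unknown key {name!r} in section {section!r}"
                )
            value = int(val) if name in _INT_KEYS else float(val)
            raw.setdefault(section, {})[name] = value
        elif key in ("theta_deg", "seed"):
            top[key] = int(val) if key == "seed" else float(val)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")

    kwargs: dict = {}
    for section, (attr, cls, _) in _SECTIONS.items():
        if section in raw:
            kwargs[attr] = cls(**raw[section])
    return PipelineConfig(**kwargs, **top)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = []
    for section, (attr, cls, keys) in _SECTIONS.items():
        obj = getattr(cfg, attr)
        if obj is None:
            continue
        for k in keys:
            v = getattr(obj, k, None)
            if v is not None:
                lines.append(f"{section}.{k} = {v}")
    lines.append(f"theta_deg = {cfg.theta_deg}")
    lines.append(f"seed = {cfg.seed}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the configuration for output headers."""
    parts = []
    for section, (attr, cls, keys) in sorted(_SECTIONS.items()):
        obj = getattr(cfg, attr)
        for k in keys:
            parts.append(f"{section}.{k}={getattr(obj, k, None)}")
    parts.append(f"theta_deg={cfg.theta_deg}")
    parts.append(f"seed={cfg.seed}")
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]
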