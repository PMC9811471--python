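"""Shared fixtures: rigs, small optics, simulated scenes."""

import math

import numpy as np
import pytest

from stereoloc.geometry import (
    Camera,
    CameraExtrinsics,
    CameraIntrinsics,
    OpticsConfig,
    StereoRig,
    rectify_rig,
    symmetric_rig,
)


@pytest.fixture(scope="session")
def rig():
    """The nominal distortion-free +/-20 degree rig."""
    return symmetric_rig()


@pytest.fixture(scope="session")
def distorted_rig():
    """Nominal rig with two-coefficient radial distortion."""
    return symmetric_rig(k1=-0.1, k2=0.05)


def make_wide_rig(k1=-0.1, k2=0.05, theta_deg=20.0, f_px=800.0, dist_mm=60.0):
    """A wide-field test rig where radial distortion is well observable
    (normalized radii up to ~0.5 at the sensor corners)."""
    th = math.radians(theta_deg)
    cams = []
    for sign in (1.0, -1.0):
        bore = np.array([sign * math.sin(th), 0.0, math.cos(th)])
        C = -dist_mm * bore
        x = np.cross([0.0, 1.0, 0.0], bore)
        x /= np.linalg.norm(x)
        y = np.cross(bore, x)
        R = np.stack([x, y, bore])
        cams.append(
            Camera(
                CameraIntrinsics(f_px, f_px, 319.5, 255.5, k1, k2),
                CameraExtrinsics(R, -R @ C),
            )
        )
    return rectify_rig(StereoRig(cams[0], cams[1], theta_deg))


@pytest.fixture(scope="session")
def wide_rig():
    return make_wide_rig()


@pytest.fixture(scope="session")
def small_optics():
    """Small sensor for fast rendered-stack tests."""
    return OpticsConfig(sensor_width=128, sensor_height=128)


@pytest.fixture(scope="session")
def small_rig(small_optics):
    return symmetric_rig(optics=small_optics)
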