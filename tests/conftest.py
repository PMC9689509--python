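"""Shared fixtures: default scene, rig, rendered views and sessions.

Rendering is the expensive step, so noise-free default renders are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from girthvision.corners import DetectorParams
from girthvision.scene import (
    BodySegmentModel,
    MarkerLayout,
    generate_measurement_session,
    make_turntable_rig,
    render_view,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return BodySegmentModel()


@pytest.fixture(scope="session")
def default_layout():
    return MarkerLayout()


@pytest.fixture(scope="session")
def default_rig():
    return make_turntable_rig()


@pytest.fixture(scope="session")
def detector():
    return DetectorParams()


@pytest.fixture(scope="session")
def clean_view(default_model, default_layout, default_rig):
    """Noise-free stereo render of the default scene at turntable angle 0."""
    left, right, gt, lmask, rmask = render_view(
        default_model, default_layout, default_rig, 0.0, seed=0
    )
    return {
        "left": left,
        "right": right,
        "gt": gt,
        "left_mask": lmask,
        "right_mask": rmask,
        "angle": 0.0,
    }


@pytest.fixture(scope="session")
def clean_session(default_model, default_layout, default_rig):
    """Noise-free four-angle session of the default (circular) body."""
    return generate_measurement_session(
        default_model, default_layout, default_rig, seed=1
    )


@pytest.fixture(scope="session")
def left_cam(default_rig):
    return default_rig.stereo.left, default_rig.left_pose


def front_facing_corners(model, gt, rig, angle, min_cos=0.35):
    """Ground-truth corners facing the left camera at a turntable angle."""
    corners = gt.corners_at(angle).reshape(-1, 3)
    cam_c = -rig.left_pose.rotation.T @ rig.left_pose.translation
    keep = []
    for c in corners:
        n = np.array([c[0] / model.a**2, c[1] / model.b**2, 0.0])
        n /= np.linalg.norm(n)
        v = cam_c - c
        v /= np.linalg.norm(v)
        if n @ v >= min_cos:
            keep.append(c)
    return np.array(keep)
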