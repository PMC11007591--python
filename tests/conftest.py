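"""Shared fixtures: the packaged field model and a synthetic camera scene."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crowgaze import head_pose as hp
from crowgaze.reference_field import reference_field_model

# ground-truth head key points (mm) used by the multi-view scene: eyes, beak
# tip, a 30 mm scale triangle near the beak root, five head markers
SCENE_POINTS = {
    "left_eye": np.array([-14.0, 2.0, 0.0]),
    "right_eye": np.array([14.0, 0.0, 1.0]),
    "beak_tip": np.array([0.0, 55.0, -8.0]),
    "scale_1": np.array([0.0, 20.0, 10.0]),
    "scale_2": np.array([30.0, 20.0, 10.0]),
    "scale_3": np.array([15.0, 20.0, 10.0 + 30.0 * np.sqrt(3) / 2]),
    "m1": np.array([0.0, 18.0, 14.0]),
    "m2": np.array([12.0, 2.0, 20.0]),
    "m3": np.array([-12.0, 2.0, 20.0]),
    "m4": np.array([8.0, -14.0, 16.0]),
    "m5": np.array([-8.0, -14.0, 12.0]),
}

CAMERA_MATRIX = np.array([[1200.0, 0.0, 960.0], [0.0, 1200.0, 540.0], [0.0, 0.0, 1.0]])

CAMERA_POSES = [
    (0.0, "x", (0.0, 0.0, 400.0)),
    (25.0, "y", (-120.0, 10.0, 420.0)),
    (-20.0, "y", (130.0, -20.0, 410.0)),
    (15.0, "x", (10.0, -100.0, 430.0)),
]


def render_view(
    angle: float,
    axis: str,
    t: tuple[float, float, float],
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> hp.CameraView:
    """Pinhole projection of the scene points into one camera."""
    Rc = Rotation.from_euler(axis, angle, degrees=True).as_matrix()
    tc = np.asarray(t, dtype=float)
    K = CAMERA_MATRIX
    ann = {}
    for lab, X in SCENE_POINTS.items():
        x = Rc @ X + tc
        u = K[0, 0] * x[0] / x[2] + K[0, 2]
        v = K[1, 1] * x[1] / x[2] + K[1, 2]
        if noise_px > 0:
            u += rng.normal(0.0, noise_px)
            v += rng.normal(0.0, noise_px)
        ann[lab] = (u, v)
    return hp.CameraView(K, ann)


def make_views(n: int = 4, noise_px: float = 0.0, rng=None) -> list[hp.CameraView]:
    return [render_view(a, ax, t, noise_px, rng) for a, ax, t in CAMERA_POSES[:n]]


@pytest.fixture(scope="session")
def reference_model():
    return reference_field_model()


@pytest.fixture(scope="session")
def exact_keypoints():
    return hp.reconstruct_keypoints(make_views(4))


@pytest.fixture(scope="session")
def calibrated_template(exact_keypoints):
    _, template = hp.define_head_frame(exact_keypoints)
    return template
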