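"""Coordinate conventions and rotation utilities.

The head-centric frame follows the motion-capture convention for a perched
bird: origin at the midpoint of the two eyes, ``x`` toward the centre of the
right eye, ``y`` toward the front (the horizon after head calibration) and
``z`` up.  Gaze and target directions are expressed as

* **azimuth** -- degrees in ``(-180, 180]``, measured from ``+y`` toward
  ``+x``; positive azimuth is toward the right eye.
* **elevation** -- degrees in ``[-90, 90]`` above the x--y plane.

Perimeter (ophthalmoscopic perimetry) coordinates describe positions on a
graduated arm centred on the same origin:

* **arm elevation** ``phi`` -- degrees in ``(-90, 270]`` in the median
  sagittal plane (0 front horizontal, 90 overhead, 180 rear horizontal).
* **arm azimuth** ``alpha`` -- degrees in ``[0, 90]`` along the arm from the
  median plane toward the lateral pole, together with a ``side``.

A useful fact used throughout: ``(phi, s)`` with ``s`` the *signed* arm
azimuth (positive toward the right pole, ``s = +alpha`` on the right arm and
``-alpha`` on the left arm) is an exact spherical coordinate system whose
pole is the ``+x`` axis, so the solid-angle element is ``cos(s) ds dphi``
and a pitch of the head about ``x`` is a pure shift of ``phi``.

All public angles are degrees; radians appear only inside computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Direction",
    "PerimeterCoordinate",
    "RigidPose",
    "direction_from_vector",
    "vector_from_direction",
    "perimeter_to_direction",
    "direction_to_perimeter",
    "axial_angle",
    "axial_angles",
    "rot_x",
    "rot_y",
    "rot_z",
    "minimal_rotation",
]

_ORTHO_TOL = 1e-6


class InvalidInputError(ValueError):
    """Raised for out-of-range or degenerate geometric inputs."""


@dataclass(frozen=True)
class Direction:
    """A head-centric viewing direction in degrees."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.azimuth <= 180.0):
            raise InvalidInputError(f"azimuth {self.azimuth} outside (-180, 180]")
        if not (-90.0 <= self.elevation <= 90.0):
            raise InvalidInputError(f"elevation {self.elevation} outside [-90, 90]")

    def as_vector(self) -> np.ndarray:
        return vector_from_direction(self)


@dataclass(frozen=True)
class PerimeterCoordinate:
    """A position on the perimetry arm (degrees)."""

    arm_elevation: float
    arm_azimuth: float
    side: Literal["left", "right"]

    def __post_init__(self) -> None:
        if not (-90.0 < self.arm_elevation <= 270.0):
            raise InvalidInputError(
                f"arm_elevation {self.arm_elevation} outside (-90, 270]"
            )
        if not (0.0 <= self.arm_azimuth <= 90.0):
            raise InvalidInputError(f"arm_azimuth {self.arm_azimuth} outside [0, 90]")
        if self.side not in ("left", "right"):
            raise InvalidInputError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class RigidPose:
    """Rotation (head frame -> world) plus world translation of the origin (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(R)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def transform(self, points_head: np.ndarray) -> np.ndarray:
        """Map head-frame points (..., 3) to world coordinates."""
        return np.asarray(points_head) @ self.rotation.T + self.translation

    def inverse_transform(self, points_world: np.ndarray) -> np.ndarray:
        return (np.asarray(points_world) - self.translation) @ self.rotation


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidInputError(f"rotation must be 3x3, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise InvalidInputError("rotation matrix is not orthonormal within tolerance")
    if np.linalg.det(R) < 0:
        raise InvalidInputError("rotation matrix is improper (det < 0)")


# ---------------------------------------------------------------------------
# direction <-> vector


def direction_from_vector(v: np.ndarray) -> Direction:
    """Direction of a (non-zero) 3-vector; azimuth 0 at the poles."""
    az, el = directions_from_vectors(np.asarray(v, dtype=float).reshape(1, 3))
    return Direction(float(az[0]), float(el[0]))


def directions_from_vectors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized: (n, 3) array -> (azimuth, elevation) degree arrays.

    Rows containing NaN propagate NaN; zero rows raise.
    """
    v = np.asarray(v, dtype=float)
    flat = v.reshape(-1, 3)
    norms = np.linalg.norm(flat, axis=1)
    finite = np.all(np.isfinite(flat), axis=1)
    if np.any(finite & (norms == 0.0)):
        raise InvalidInputError("zero vector has no direction")
    with np.errstate(invalid="ignore", divide="ignore"):
        el = np.degrees(np.arcsin(np.clip(flat[:, 2] / norms, -1.0, 1.0)))
        az = np.degrees(np.arctan2(flat[:, 0], flat[:, 1]))
    # pole convention: azimuth defined as 0 where the horizontal projection vanishes
    at_pole = finite & (np.hypot(flat[:, 0], flat[:, 1]) == 0.0)
    az[at_pole] = 0.0
    # atan2(0, -1) gives +180 which is in range; -180 never occurs
    shape = v.shape[:-1]
    return az.reshape(shape), el.reshape(shape)


def vector_from_direction(d: Direction | tuple[float, float]) -> np.ndarray:
    """Unit vector for a direction (inverse of :func:`direction_from_vector`)."""
    if isinstance(d, Direction):
        az, el = d.azimuth, d.elevation
    else:
        az, el = d
        Direction(az, el)  # range validation
    return vectors_from_directions(np.asarray([az]), np.asarray([el]))[0]


def vectors_from_directions(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    """Vectorized inverse: degree arrays -> (n, 3) unit vectors."""
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)], axis=-1
    )


# ---------------------------------------------------------------------------
# perimeter coordinates


def perimeter_to_direction(p: PerimeterCoordinate) -> Direction:
    """Head-centric direction of a point on the perimetry arm."""
    phi = np.radians(p.arm_elevation)
    alpha = np.radians(p.arm_azimuth)
    sign = 1.0 if p.side == "right" else -1.0
    v = np.array(
        [sign * np.sin(alpha), np.cos(alpha) * np.cos(phi), np.cos(alpha) * np.sin(phi)]
    )
    return direction_from_vector(v)


def direction_to_perimeter(d: Direction) -> PerimeterCoordinate:
    """Inverse of :func:`perimeter_to_direction` (side 'right' when on the midline)."""
    v = vector_from_direction(d)
    phi, s = arm_coordinates(v.reshape(1, 3))
    side = "right" if s[0] >= 0 else "left"
    return PerimeterCoordinate(float(phi[0]), float(abs(s[0])), side)


def arm_coordinates(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed arm coordinates ``(phi, s)`` of vectors (..., 3).

    ``phi`` in ``(-90, 270]`` is the sagittal angle of the arm through the
    point; ``s`` in ``[-90, 90]`` is the angle along the arm from the median
    plane, positive toward the right pole (+x).  Exactly the spherical
    coordinates with pole +x.  At the poles (|s| = 90) ``phi`` is set to 0.
    """
    v = np.asarray(v, dtype=float)
    flat = v.reshape(-1, 3)
    norms = np.linalg.norm(flat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.degrees(np.arcsin(np.clip(flat[:, 0] / norms, -1.0, 1.0)))
        phi = np.degrees(np.arctan2(flat[:, 2], flat[:, 1]))
    phi = np.where(phi <= -90.0, phi + 360.0, phi)
    at_pole = np.hypot(flat[:, 1], flat[:, 2]) == 0.0
    phi = np.where(at_pole, 0.0, phi)
    shape = v.shape[:-1]
    return phi.reshape(shape), s.reshape(shape)


def vector_from_arm(phi_deg: np.ndarray, s_deg: np.ndarray) -> np.ndarray:
    """Unit vectors from signed arm coordinates (inverse of arm_coordinates)."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    s = np.radians(np.asarray(s_deg, dtype=float))
    return np.stack(
        [np.sin(s), np.cos(s) * np.cos(phi), np.cos(s) * np.sin(phi)], axis=-1
    )


# ---------------------------------------------------------------------------
# rotations


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def axial_angle(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Rotation angle (deg) of the relative rotation ``Rb @ Ra.T``.

    The geodesic distance on SO(3); symmetric in its arguments.
    """
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    _check_rotation(Ra)
    _check_rotation(Rb)
    rel = Rb @ Ra.T
    cos_theta = np.clip((np.trace(rel) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def axial_angles(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Vectorized axial angle for stacks of rotations (n, 3, 3)."""
    rel = np.einsum("nij,nkj->nik", np.asarray(Rb, float), np.asarray(Ra, float))
    tr = np.einsum("nii->n", rel)
    return np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


def minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector ``v_from`` to ``v_to``.

    Rodrigues about ``v_from x v_to``; for antiparallel inputs an arbitrary
    but deterministic perpendicular axis is used.
    """
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / n
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    s = n
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)
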