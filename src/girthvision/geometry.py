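"""Pinhole projection, binocular triangulation and turntable de-rotation.

Conventions used throughout the package:

* pixel coordinates are 0-based, continuous, with the origin at the centre of
  the top-left pixel; ``x`` grows rightward, ``y`` grows downward;
* 3-D frames are right-handed; the camera looks along its own +z axis with
  +x rightward and +y downward (so the image axes match the camera axes);
* all lengths are metres, all angles degrees unless stated otherwise.

The stereo rig is anchored to the left camera: 3-D points triangulated from a
pixel pair are expressed in the left-camera frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "StereoRig",
    "Point3DSet",
    "BehindCameraError",
    "DegenerateGeometryError",
    "project",
    "triangulate",
    "reverse_rotate",
    "rotation_about_axis",
    "load_rig",
    "save_rig",
]

_ORTHO_TOL = 1e-9


class BehindCameraError(ValueError):
    """Raised when a point to be projected has non-positive camera depth."""


class DegenerateGeometryError(ValueError):
    """Raised when triangulation rays are (near-)parallel."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    focal_x: float
    focal_y: float
    principal_x: float
    principal_y: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.principal_x < self.image_width):
            raise ValueError("principal_x outside image bounds")
        if not (0 <= self.principal_y < self.image_height):
            raise ValueError("principal_y outside image bounds")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix K."""
        return np.array(
            [
                [self.focal_x, 0.0, self.principal_x],
                [0.0, self.focal_y, self.principal_y],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class StereoRig:
    """Calibrated binocular rig: two pinhole cameras plus their relative pose.

    ``right_from_left`` maps left-camera coordinates into the right-camera
    frame.  ``shooting_distance_D`` is the nominal camera-to-subject distance
    used by the checkerboard pixel-step model.
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    right_from_left: RigidTransform
    shooting_distance_D: float

    def __post_init__(self) -> None:
        if np.linalg.norm(self.right_from_left.translation) <= 0:
            raise ValueError("baseline length must be positive")
        if self.shooting_distance_D <= 0:
            raise ValueError("shooting distance must be positive")

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.right_from_left.translation))


@dataclass
class Point3DSet:
    """Reconstructed 3-D points tagged with source line index and view angle."""

    points: np.ndarray
    line_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    angle: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts
        n = len(pts)
        if self.line_index is None:
            self.line_index = np.zeros(n, dtype=int)
        else:
            self.line_index = np.asarray(self.line_index, dtype=int).reshape(n)
        if self.angle is None:
            self.angle = np.zeros(n, dtype=float)
        else:
            self.angle = np.asarray(self.angle, dtype=float).reshape(n)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def concatenate(cls, sets: "list[Point3DSet]") -> "Point3DSet":
        return cls(
            np.concatenate([s.points for s in sets], axis=0),
            np.concatenate([s.line_index for s in sets]),
            np.concatenate([s.angle for s in sets]),
        )


def project(
    point: np.ndarray,
    camera: CameraIntrinsics,
    pose: RigidTransform | None = None,
) -> np.ndarray:
    """Project 3-D point(s) into continuous pixel coordinates.

    ``pose`` maps world coordinates into the camera frame (camera-from-world);
    omit it for points already expressed in the camera frame.  Raises
    :class:`BehindCameraError` for non-positive depth.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    if pose is not None:
        pts = pose.apply(pts)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("point behind camera (non-positive depth)")
    u = camera.focal_x * pts[:, 0] / z + camera.principal_x
    v = camera.focal_y * pts[:, 1] / z + camera.principal_y
    pix = np.stack([u, v], axis=-1)
    return pix[0] if single else pix


def _backproject_dir(pix: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    d = np.array(
        [
            (pix[0] - cam.principal_x) / cam.focal_x,
            (pix[1] - cam.principal_y) / cam.focal_y,
            1.0,
        ]
    )
    return d / np.linalg.norm(d)


def triangulate(pix_left: np.ndarray, pix_right: np.ndarray, rig: StereoRig) -> np.ndarray:
    """Triangulate a pixel pair as the midpoint of the common perpendicular.

    The two viewing rays are back-projected in the left-camera frame; the
    returned 3-D point is the midpoint of the shortest segment joining them.
    Raises :class:`DegenerateGeometryError` when the rays are near-parallel.
    """
    pl = np.asarray(pix_left, dtype=float).reshape(2)
    pr = np.asarray(pix_right, dtype=float).reshape(2)
    if not (np.all(np.isfinite(pl)) and np.all(np.isfinite(pr))):
        raise ValueError("pixel coordinates must be finite")

    d1 = _backproject_dir(pl, rig.left)  # ray through left centre (origin)
    left_from_right = rig.right_from_left.inverse()
    o2 = left_from_right.translation  # right camera centre in left frame
    d2 = left_from_right.rotation @ _backproject_dir(pr, rig.right)

    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < 1e-6:
        raise DegenerateGeometryError("viewing rays are near-parallel")

    # Solve for s, t on p1 = s d1, p2 = o2 + t d2 minimising |p1 - p2|.
    b = d1 @ d2
    w = -o2
    s = (-(w @ d1) + (w @ d2) * b) / (1.0 - b * b)
    t = ((w @ d2) - (w @ d1) * b) / (1.0 - b * b)
    p1 = s * d1
    p2 = o2 + t * d2
    return 0.5 * (p1 + p2)


def rotation_about_axis(angle_deg: float, axis_dir: np.ndarray) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    n = np.asarray(axis_dir, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm < _ORTHO_TOL:
        raise ValueError("invalid axis: zero-length direction")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("axis direction must be a unit vector")
    theta = np.deg2rad(angle_deg)
    K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def reverse_rotate(
    points: Point3DSet,
    angle_deg: float,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
) -> Point3DSet:
    """Undo a turntable rotation: rotate points by ``-angle`` about the axis.

    Points captured after the turntable turned by ``angle`` are returned to
    their initial positions so multi-view reconstructions share one frame.
    """
    R = rotation_about_axis(-angle_deg, axis_dir)
    c = np.asarray(axis_point, dtype=float).reshape(3)
    rotated = (points.points - c) @ R.T + c
    return Point3DSet(rotated, points.line_index.copy(), points.angle.copy())


# ---------------------------------------------------------------------------
# calibration file round-trip


def save_rig(rig: StereoRig, path) -> None:
    """Write a stereo rig to a plain-text YAML calibration file."""

    def cam(c: CameraIntrinsics) -> dict:
        return {
            "fx": float(c.focal_x),
            "fy": float(c.focal_y),
            "cx": float(c.principal_x),
            "cy": float(c.principal_y),
            "width": int(c.image_width),
            "height": int(c.image_height),
        }

    doc = {
        "left": cam(rig.left),
        "right": cam(rig.right),
        "right_from_left": {
            "rotation": [[float(v) for v in row] for row in rig.right_from_left.rotation],
            "translation": [float(v) for v in rig.right_from_left.translation],
        },
        "shooting_distance_D": float(rig.shooting_distance_D),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_rig(path) -> StereoRig:
    """Read a stereo rig from the YAML calibration file written by save_rig."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def cam(d: dict) -> CameraIntrinsics:
        return CameraIntrinsics(
            d["fx"], d["fy"], d["cx"], d["cy"], d["width"], d["height"]
        )

    rel = doc["right_from_left"]
    return StereoRig(
        left=cam(doc["left"]),
        right=cam(doc["right"]),
        right_from_left=RigidTransform(
            np.array(rel["rotation"]), np.array(rel["translation"])
        ),
        shooting_distance_D=doc["shooting_distance_D"],
    )
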