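"""Synthetic stereo turntable scene with exact analytic ground truth.

The simulator emulates the measurement setup of a checkerboard-suited body
segment on a turntable: an elliptic cylinder whose surface carries a black
and white checkerboard laid out by arc length (2.5 cm vertical interval;
circumferential cells stretched uniformly so an even number of cells closes
the loop), four red/cyan marker cells spaced roughly a quarter turn apart,
and a calibrated, slightly verged stereo rig at shooting distance D.
Rendering is analytic ray/ellipse-cylinder intersection per (supersampled)
pixel — no external renderer — so every corner's 3-D position, every marker
centre and the true cross-section girth are known exactly.

Four turntable angles bring the four marker pairs successively to face the
cameras; together the marker-pair rectangles tile the full circumference, so
the union of the per-view constrained corner rows covers 360 degrees of the
measurement line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import imageio.v3 as iio

from .geometry import (
    CameraIntrinsics,
    RigidTransform,
    StereoRig,
    project,
    rotation_about_axis,
)

__all__ = [
    "BodySegmentModel",
    "MarkerLayout",
    "SceneGroundTruth",
    "TurntableRig",
    "ViewData",
    "MeasurementSession",
    "OutOfViewError",
    "make_turntable_rig",
    "render_view",
    "generate_measurement_session",
    "generate_segmentation_fixtures",
    "azimuth_coverage_deg",
    "identify_corner",
    "count_mismatches",
    "save_session",
]

# flat shading palette (8-bit RGB); chosen so each class falls inside the
# corresponding HSV window and nothing else does
COLOR_WHITE = np.array([240, 240, 240], dtype=np.uint8)
COLOR_BLACK = np.array([20, 20, 20], dtype=np.uint8)
COLOR_RED = np.array([230, 25, 25], dtype=np.uint8)
COLOR_CYAN = np.array([25, 230, 230], dtype=np.uint8)
COLOR_BG = np.array([128, 128, 128], dtype=np.uint8)


class OutOfViewError(ValueError):
    """Raised when the body segment is not fully visible in both cameras."""


@dataclass(frozen=True)
class BodySegmentModel:
    """Elliptic-cylinder body segment dressed in a checkerboard.

    ``a``/``b`` are the cross-section semi-axes (metres); the cylinder axis
    is the world z-axis through the origin.  ``checkerboard_interval`` is the
    vertical corner spacing; circumferentially the perimeter is divided into
    the nearest even number of cells of (almost) the same size, mimicking a
    stretched garment while keeping the wrapped pattern alternating.
    """

    a: float = 0.13
    b: float = 0.13
    z_range: tuple = (-0.10, 0.08)
    checkerboard_interval: float = 0.025
    baseline_z: float = 0.0  # height of the reference corner row

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.checkerboard_interval <= 0:
            raise ValueError("checkerboard interval must be positive")
        if self.z_range[0] >= self.z_range[1]:
            raise ValueError("empty height range")

    @property
    def perimeter(self) -> float:
        """Cross-section circumference via dense arc-length quadrature."""
        _, s_grid = self._arc_table()
        return float(s_grid[-1])

    def _arc_table(self, m: int = 8192):
        cached = self.__dict__.get("_arc_cache")
        if cached is not None and len(cached[0]) == m + 1:
            return cached
        u = np.linspace(0.0, 2 * np.pi, m + 1)
        integrand = np.sqrt(
            (self.a * np.sin(u)) ** 2 + (self.b * np.cos(u)) ** 2
        )
        # cumulative trapezoid
        s = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(u))]
        )
        object.__setattr__(self, "_arc_cache", (u, s))
        return u, s

    @property
    def n_cells(self) -> int:
        """Circumferential cell count: nearest even integer to P / interval."""
        n = self.perimeter / self.checkerboard_interval
        return max(4, int(round(n / 2.0)) * 2)

    @property
    def cell_arc(self) -> float:
        return self.perimeter / self.n_cells

    def s_of_u(self, u: np.ndarray) -> np.ndarray:
        ug, sg = self._arc_table()
        return np.interp(np.mod(u, 2 * np.pi), ug, sg)

    def u_of_s(self, s: np.ndarray) -> np.ndarray:
        ug, sg = self._arc_table()
        return np.interp(np.mod(s, sg[-1]), sg, ug)

    def surface_point(self, col: np.ndarray, row: np.ndarray, c_ref: float,
                      u_face: float) -> np.ndarray:
        """Body-frame 3-D point of texture coordinates (col, row)."""
        s = self.s_of_u(np.array(u_face)) - (np.asarray(col, float) - c_ref) * self.cell_arc
        u = self.u_of_s(s)
        z = self.baseline_z - np.asarray(row, float) * self.checkerboard_interval
        return np.stack(
            [self.a * np.cos(u), self.b * np.sin(u), np.broadcast_to(z, u.shape)],
            axis=-1,
        )


def _quarter_offsets(n: int) -> tuple:
    return tuple(ceil((k + 1) * n / 4) - ceil(k * n / 4) for k in range(4))


@dataclass(frozen=True)
class MarkerLayout:
    """Placement of the four red/cyan marker cells on the checkerboard grid.

    ``horizontal_offsets`` are the circumferential distances (in checkerboard
    intervals) from each marker to the next; they must sum to the cell count
    and default to the near-quarter split — (8, 7, 8, 7) on a 30-cell
    garment.  ``vertical_offsets`` are the row distances between successive
    markers, (-1, +1, -1, +1) by default, so every marker pair straddles the
    same baseline corner row.  Markers alternate red/cyan and fill one whole
    checkerboard cell each unless a smaller ``marker_radius`` (metres) is
    given.
    """

    horizontal_offsets: tuple | None = None
    vertical_offsets: tuple = (-1, 1, -1, 1)
    first_row: float = 0.5
    base_col: float = 0.0
    marker_radius: float | None = None

    def resolved_offsets(self, n_cells: int) -> tuple:
        offs = self.horizontal_offsets
        if offs is None:
            offs = _quarter_offsets(n_cells)
        if len(offs) != 4 or sum(offs) != n_cells:
            raise ValueError(
                f"horizontal offsets {offs} must be 4 values summing to the "
                f"cell count {n_cells}"
            )
        return tuple(offs)

    def marker_cols(self, n_cells: int) -> np.ndarray:
        offs = self.resolved_offsets(n_cells)
        cum = np.concatenate([[0], np.cumsum(offs)[:-1]])
        return self.base_col + cum - 0.5

    def marker_rows(self) -> np.ndarray:
        rows = [self.first_row]
        for v in self.vertical_offsets[:3]:
            rows.append(rows[-1] + v)
        back = rows[-1] + self.vertical_offsets[3]
        if not np.isclose(back, rows[0]):
            raise ValueError("vertical offsets must return to the first row")
        return np.array(rows)

    @property
    def marker_colors(self) -> tuple:
        return ("red", "cyan", "red", "cyan")


@dataclass
class TurntableRig:
    """Stereo rig plus its pose relative to the turntable axis (world z)."""

    stereo: StereoRig
    left_pose: RigidTransform  # camera-from-world
    right_pose: RigidTransform

    @property
    def axis_point_left(self) -> np.ndarray:
        """Turntable axis point expressed in the left-camera frame."""
        return self.left_pose.apply(np.zeros(3))

    @property
    def axis_dir_left(self) -> np.ndarray:
        d = self.left_pose.rotation @ np.array([0.0, 0.0, 1.0])
        return d / np.linalg.norm(d)


def _look_at(center: np.ndarray, target: np.ndarray) -> RigidTransform:
    z = target - center
    z = z / np.linalg.norm(z)
    down = np.array([0.0, 0.0, -1.0])
    x = np.cross(down, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R_wc = np.stack([x, y, z], axis=1)  # world-from-camera rotation
    R_cw = R_wc.T
    return RigidTransform(R_cw, -R_cw @ center)


def make_turntable_rig(
    shooting_distance: float = 2.4,
    baseline: float = 0.16,
    focal: float = 2400.0,
    width: int = 640,
    height: int = 480,
    verged: bool = True,
    camera_height: float = 0.0,
) -> TurntableRig:
    """Build the default calibrated rig: two identical pinhole cameras at
    distance D from the turntable axis, baseline horizontal, slightly verged
    on the axis (or parallel)."""
    intr = CameraIntrinsics(focal, focal, (width - 1) / 2, (height - 1) / 2, width, height)
    cl = np.array([-baseline / 2, -shooting_distance, camera_height])
    cr = np.array([baseline / 2, -shooting_distance, camera_height])
    target = np.array([0.0, 0.0, camera_height])
    if verged:
        left_pose = _look_at(cl, target)
        right_pose = _look_at(cr, target)
    else:
        fwd = _look_at(np.array([0.0, -shooting_distance, camera_height]), target)
        left_pose = RigidTransform(fwd.rotation, -fwd.rotation @ cl)
        right_pose = RigidTransform(fwd.rotation, -fwd.rotation @ cr)
    right_from_left = right_pose.compose(left_pose.inverse())
    stereo = StereoRig(intr, intr, right_from_left, shooting_distance)
    return TurntableRig(stereo, left_pose, right_pose)


@dataclass
class SceneGroundTruth:
    """Exact analytic truth for one rendered view or a whole session."""

    girth_m: float
    corner_rows: np.ndarray  # grid rows carried in `corners_initial`
    corners_initial: np.ndarray  # (n_rows, n_cells, 3), turntable at 0
    corner_normals_initial: np.ndarray  # outward unit normals, same shape
    marker_centers_initial: np.ndarray  # (4, 3)
    marker_colors: tuple
    interior_cols_per_pair: list  # integer corner columns inside each pair
    n_cells: int
    facing_angles: np.ndarray  # turntable angle that faces each pair (deg)

    def corners_at(self, angle_deg: float) -> np.ndarray:
        R = rotation_about_axis(angle_deg, np.array([0.0, 0.0, 1.0]))
        return self.corners_initial @ R.T

    def normals_at(self, angle_deg: float) -> np.ndarray:
        R = rotation_about_axis(angle_deg, np.array([0.0, 0.0, 1.0]))
        return self.corner_normals_initial @ R.T

    def markers_at(self, angle_deg: float) -> np.ndarray:
        R = rotation_about_axis(angle_deg, np.array([0.0, 0.0, 1.0]))
        return self.marker_centers_initial @ R.T


@dataclass
class ViewData:
    angle: float
    left_image: np.ndarray
    right_image: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    pair_index: int = 0


@dataclass
class MeasurementSession:
    """Bundle of everything one simulated measurement produces."""

    model: BodySegmentModel
    layout: MarkerLayout
    rig: TurntableRig
    views: list
    ground_truth: SceneGroundTruth
    seed: int = 0
    noise_sigma: float = 0.0
    body_part: str = "waist"


def _texture_frame(model: BodySegmentModel, layout: MarkerLayout):
    """Reference constants tying texture columns to body azimuth.

    The first marker pair's centre column faces the cameras (azimuth -90
    degrees, the -y direction) when the turntable angle is zero; columns
    increase clockwise when seen from above so that positive turntable
    rotation brings later pairs into view.
    """
    n = model.n_cells
    offs = layout.resolved_offsets(n)
    mcols = layout.marker_cols(n)
    c_ref = 0.5 * (mcols[0] + mcols[1])
    u_face = -np.pi / 2.0
    pair_centers = np.array(
        [0.5 * (mcols[k] + (mcols[(k + 1) % 4] if k < 3 else mcols[0] + n)) for k in range(4)]
    )
    facing = (pair_centers - c_ref) * (360.0 / n)
    return n, offs, mcols, c_ref, u_face, facing


def _col_of_points(model, c_ref, u_face, x, y):
    u = np.arctan2(y / model.b, x / model.a)
    s = model.s_of_u(u)
    s_face = model.s_of_u(np.array(u_face))
    return c_ref + (s_face - s) / model.cell_arc  # wrapped later mod n


def _build_ground_truth(
    model: BodySegmentModel, layout: MarkerLayout, rows
) -> SceneGroundTruth:
    n, offs, mcols, c_ref, u_face, facing = _texture_frame(model, layout)
    rows = np.asarray(rows, dtype=float)
    cols = np.arange(n, dtype=float)
    cgrid, rgrid = np.meshgrid(cols, rows)
    corners = model.surface_point(cgrid, rgrid, c_ref, u_face)
    normals = np.stack(
        [corners[..., 0] / model.a**2, corners[..., 1] / model.b**2,
         np.zeros_like(corners[..., 0])],
        axis=-1,
    )
    normals /= np.linalg.norm(normals, axis=-1, keepdims=True)
    mrows = layout.marker_rows()
    markers = model.surface_point(mcols, mrows, c_ref, u_face)
    cum = np.concatenate([[0], np.cumsum(offs)[:-1]])
    interior = [
        (np.arange(cum[k], cum[k] + offs[k]) % n).astype(int) for k in range(4)
    ]
    return SceneGroundTruth(
        girth_m=model.perimeter,
        corner_rows=rows,
        corners_initial=corners,
        corner_normals_initial=normals,
        marker_centers_initial=markers,
        marker_colors=layout.marker_colors,
        interior_cols_per_pair=interior,
        n_cells=n,
        facing_angles=facing,
    )


def _render_camera(
    model: BodySegmentModel,
    layout: MarkerLayout,
    cam: CameraIntrinsics,
    pose: RigidTransform,
    angle_deg: float,
    supersample: int,
    rng: np.random.Generator | None,
    noise_sigma: float,
):
    n, offs, mcols, c_ref, u_face, _ = _texture_frame(model, layout)
    mrows = layout.marker_rows()

    ss = max(1, int(supersample))
    W, H = cam.image_width, cam.image_height
    # subpixel sample coordinates (pixel centres at integers)
    base = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(W)[:, None] + base[None, :]).ravel()
    ys = (np.arange(H)[:, None] + base[None, :]).ravel()
    X, Y = np.meshgrid(xs, ys)

    # rays in world frame
    R_wc = pose.rotation.T
    center = -R_wc @ pose.translation
    dx = (X - cam.principal_x) / cam.focal_x
    dy = (Y - cam.principal_y) / cam.focal_y
    d_world = (
        R_wc[:, 0][None, None, :] * dx[..., None]
        + R_wc[:, 1][None, None, :] * dy[..., None]
        + R_wc[:, 2][None, None, :]
    )

    # into the (rotated) body frame
    Rb = rotation_about_axis(-angle_deg, np.array([0.0, 0.0, 1.0]))
    o = Rb @ center
    d = d_world @ Rb.T

    a2, b2 = model.a**2, model.b**2
    A = d[..., 0] ** 2 / a2 + d[..., 1] ** 2 / b2
    B = 2 * (o[0] * d[..., 0] / a2 + o[1] * d[..., 1] / b2)
    C = o[0] ** 2 / a2 + o[1] ** 2 / b2 - 1.0
    disc = B * B - 4 * A * C
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t = (-B - sq) / (2 * A)
    z = o[2] + t * d[..., 2]
    hit &= (t > 1e-6) & (z >= model.z_range[0]) & (z <= model.z_range[1])

    px = o[0] + t * d[..., 0]
    py = o[1] + t * d[..., 1]
    col = _col_of_points(model, c_ref, u_face, px, py)
    row = (model.baseline_z - z) / model.checkerboard_interval

    img = np.empty(hit.shape + (3,), dtype=float)
    img[...] = COLOR_BG
    parity = (np.floor(np.mod(col, n)) + np.floor(row)).astype(int) % 2
    img[hit & (parity == 0)] = COLOR_WHITE
    img[hit & (parity == 1)] = COLOR_BLACK

    for mc, mr, color in zip(mcols, mrows, layout.marker_colors):
        dcol = np.mod(col - mc + n / 2, n) - n / 2
        drow = row - mr
        if layout.marker_radius is None:
            inside = (np.abs(dcol) < 0.5) & (np.abs(drow) < 0.5)
        else:
            rad_cells = layout.marker_radius / model.checkerboard_interval
            rad_cols = layout.marker_radius / model.cell_arc
            inside = (dcol / rad_cols) ** 2 + (drow / rad_cells) ** 2 < 1.0
        sel = hit & inside
        img[sel] = COLOR_RED if color == "red" else COLOR_CYAN

    # box-average the supersamples back to pixel resolution
    img = img.reshape(H, ss, W, ss, 3).mean(axis=(1, 3))
    mask = hit.reshape(H, ss, W, ss).mean(axis=(1, 3)) > 0.5
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requested without a random generator")
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def _check_in_view(model: BodySegmentModel, rig: TurntableRig) -> None:
    z0, z1 = model.z_range
    extremes = np.array(
        [
            [sx * model.a, sy * model.b, zz]
            for sx in (-1, 1)
            for sy in (-1, 1)
            for zz in (z0, z1)
        ]
    )
    for cam, pose in ((rig.stereo.left, rig.left_pose), (rig.stereo.right, rig.right_pose)):
        pix = project(extremes, cam, pose)
        if (
            pix[:, 0].min() < 0
            or pix[:, 0].max() > cam.image_width - 1
            or pix[:, 1].min() < 0
            or pix[:, 1].max() > cam.image_height - 1
        ):
            raise OutOfViewError("out of view: body segment exceeds a camera frustum")


def render_view(
    model: BodySegmentModel,
    layout: MarkerLayout,
    rig: TurntableRig,
    turntable_angle: float,
    seed: int = 0,
    noise_sigma: float = 0.0,
    supersample: int = 3,
    gt_rows=(-3, -2, -1, 0, 1, 2, 3),
):
    """Render one stereo pair at a turntable angle.

    Returns ``(left_image, right_image, ground_truth, left_mask, right_mask)``
    with 8-bit RGB images, boolean body masks and the exact analytic ground
    truth (corner/marker 3-D positions at turntable zero; rotate with
    :meth:`SceneGroundTruth.corners_at`).
    """
    _check_in_view(model, rig)
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(round(turntable_angle * 1000)) & 0x7FFFFFFF]))
    left, lmask = _render_camera(
        model, layout, rig.stereo.left, rig.left_pose, turntable_angle,
        supersample, rng, noise_sigma,
    )
    right, rmask = _render_camera(
        model, layout, rig.stereo.right, rig.right_pose, turntable_angle,
        supersample, rng, noise_sigma,
    )
    gt = _build_ground_truth(model, layout, gt_rows)
    return left, right, gt, lmask, rmask


def generate_measurement_session(
    model: BodySegmentModel,
    layout: MarkerLayout,
    rig: TurntableRig,
    angles=None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    supersample: int = 3,
    body_part: str = "waist",
) -> MeasurementSession:
    """Render the full four-angle measurement session.

    ``angles=None`` uses the pair-facing angles (0/90/180/270 degrees for the
    default layout).  Deterministic for a fixed seed.
    """
    gt = _build_ground_truth(model, layout, rows=(-3, -2, -1, 0, 1, 2, 3))
    if angles is None:
        angles = [float(a) for a in gt.facing_angles]
    if len(angles) < 2:
        raise ValueError("insufficient coverage: need at least 2 turntable angles")
    if len(set(float(a) % 360 for a in angles)) != len(angles):
        raise ValueError("turntable angles must be distinct")
    views = []
    for k, ang in enumerate(angles):
        left, right, _, lmask, rmask = render_view(
            model, layout, rig, ang, seed=seed, noise_sigma=noise_sigma,
            supersample=supersample,
        )
        views.append(
            ViewData(
                angle=float(ang),
                left_image=left,
                right_image=right,
                left_mask=lmask,
                right_mask=rmask,
                pair_index=k,
            )
        )
    return MeasurementSession(
        model=model,
        layout=layout,
        rig=rig,
        views=views,
        ground_truth=gt,
        seed=seed,
        noise_sigma=noise_sigma,
        body_part=body_part,
    )


def azimuth_coverage_deg(
    points: np.ndarray,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
    gap_tol_deg: float = 30.0,
) -> float:
    """Angular coverage of a point set about an axis, in degrees.

    Azimuths are sorted around the circle; each gap between consecutive
    samples contributes at most ``gap_tol_deg`` to the total, so a set whose
    largest gap stays below the tolerance covers the full 360 degrees.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3) - np.asarray(axis_point, float)
    nrm = np.asarray(axis_dir, float)
    nrm = nrm / np.linalg.norm(nrm)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ nrm) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ nrm) * nrm
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    az = np.degrees(np.arctan2(pts @ e2, pts @ e1))
    az = np.sort(np.mod(az, 360.0))
    if len(az) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    return float(np.sum(np.minimum(gaps, gap_tol_deg)))


def identify_corner(
    pixel,
    gt: SceneGroundTruth,
    angle_deg: float,
    cam: CameraIntrinsics,
    pose: RigidTransform,
    tol_px: float = 1.5,
):
    """Identify which ground-truth corner a detected pixel corresponds to.

    Projects every ground-truth corner at the given turntable angle into the
    camera and returns the (row, col) grid identity of the nearest one within
    ``tol_px`` pixels, or ``None``.  This is the simulator's correspondence
    oracle: a matched stereo pair is correct exactly when both members
    identify as the same grid corner.
    """
    corners = gt.corners_at(angle_deg)
    normals = gt.normals_at(angle_deg)
    n_rows, n_cols, _ = corners.shape
    flat = corners.reshape(-1, 3)
    cam_pts = pose.apply(flat)
    # visible = in front of the camera and on the camera-facing surface
    cam_center = -pose.rotation.T @ pose.translation
    view_dirs = cam_center[None, :] - flat
    view_dirs /= np.linalg.norm(view_dirs, axis=1, keepdims=True)
    facing = np.sum(normals.reshape(-1, 3) * view_dirs, axis=1) > 0.05
    vis = (cam_pts[:, 2] > 0) & facing
    pix = np.full((len(flat), 2), np.inf)
    pix[vis] = project(flat[vis], cam, pose)
    d = np.hypot(pix[:, 0] - pixel[0], pix[:, 1] - pixel[1])
    i = int(np.argmin(d))
    if d[i] > tol_px:
        return None
    return (float(gt.corner_rows[i // n_cols]), int(i % n_cols))


def count_mismatches(
    pairs,
    gt: SceneGroundTruth,
    rig: TurntableRig,
    tol_px: float = 1.5,
) -> tuple:
    """Number of mismatched pairs in a MatchedPairList, per the oracle.

    A pair is mismatched when its left and right members identify as
    different ground-truth corners (or cannot be identified at all).
    Returns ``(n_mismatched, n_pairs)``.
    """
    bad = 0
    for i in range(len(pairs)):
        idl = identify_corner(pairs.left_xy[i], gt, pairs.angle,
                              rig.stereo.left, rig.left_pose, tol_px)
        idr = identify_corner(pairs.right_xy[i], gt, pairs.angle,
                              rig.stereo.right, rig.right_pose, tol_px)
        if idl is None or idr is None or idl != idr:
            bad += 1
    return bad, len(pairs)


# ---------------------------------------------------------------------------
# segmentation training fixtures


def generate_segmentation_fixtures(n: int, image_size: int = 64, seed: int = 0):
    """Procedural two-class (background / body-region) training fixtures.

    Each fixture is an RGB image containing one soft-edged elliptical body
    silhouette over a darker noisy background, with randomised position,
    size, orientation, brightness and colour cast.  Returned as a list of
    ``(image, mask)`` with ``image`` float32 of shape (3, H, W) in [0, 1] and
    ``mask`` int64 of shape (H, W) holding class indices {0, 1}.
    """
    if n < 1:
        raise ValueError("invalid count: n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    h = w = int(image_size)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy = rng.uniform(0.35, 0.65) * h
        cx = rng.uniform(0.35, 0.65) * w
        ry = rng.uniform(0.20, 0.38) * h
        rx = rng.uniform(0.14, 0.30) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        dx, dy = xx - cx, yy - cy
        r2 = ((dx * ct + dy * st) / rx) ** 2 + ((-dx * st + dy * ct) / ry) ** 2
        mask = (r2 < 1.0).astype(np.int64)
        fg = rng.uniform(0.60, 0.85)
        bg = rng.uniform(0.15, 0.40)
        cast = rng.uniform(0.9, 1.1, size=3)
        img = np.where(mask[None] == 1, fg, bg) * cast[:, None, None]
        img = img + rng.normal(0.0, 0.08, size=(3, h, w))
        out.append((np.clip(img, 0, 1).astype(np.float32), mask))
    return out


# ---------------------------------------------------------------------------
# session persistence (plain-text / PNG artifacts)


def save_session(session: MeasurementSession, directory) -> None:
    """Write a session to disk: PNG images and masks plus a JSON ground truth."""
    import os

    os.makedirs(directory, exist_ok=True)
    for v in session.views:
        tag = f"view{v.pair_index}_a{int(round(v.angle)):03d}"
        iio.imwrite(os.path.join(directory, f"{tag}_left.png"), v.left_image)
        iio.imwrite(os.path.join(directory, f"{tag}_right.png"), v.right_image)
        iio.imwrite(
            os.path.join(directory, f"{tag}_left_mask.png"),
            v.left_mask.astype(np.uint8) * 255,
        )
        iio.imwrite(
            os.path.join(directory, f"{tag}_right_mask.png"),
            v.right_mask.astype(np.uint8) * 255,
        )
    gt = session.ground_truth
    doc = {
        "girth_m": gt.girth_m,
        "n_cells": gt.n_cells,
        "corner_rows": gt.corner_rows.tolist(),
        "corners_initial": gt.corners_initial.tolist(),
        "marker_centers_initial": gt.marker_centers_initial.tolist(),
        "marker_colors": list(gt.marker_colors),
        "facing_angles": gt.facing_angles.tolist(),
        "angles": [v.angle for v in session.views],
        "seed": session.seed,
        "noise_sigma": session.noise_sigma,
        "body_part": session.body_part,
    }
    with open(os.path.join(directory, "ground_truth.json"), "w") as fh:
        json.dump(doc, fh, indent=1)
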