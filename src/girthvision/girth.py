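"""From matched corner pairs to girths: triangulation, turntable de-rotation,
closed-curve circumference fitting and measurement selection.

The circumference of a measurement line is obtained by projecting the
reconstructed 3-D corners onto the plane normal to the body axis, ordering
them by azimuth, fitting a periodic piecewise-cubic closed curve in an
intermediate arc-length parameter, and integrating its arc length.  This is
a documented surrogate for polynomial-with-intermediate-variable curve
fitting (PIVCF); the fitting function is pluggable so an alternative closed
curve model can be slotted in.

Per garment-measurement practice, three adjacent lines are measured and the
maximum is reported for bust, hip and thigh, the minimum for the waist; the
under-bust and mid-thigh are read from a third line shifted two checkerboard
steps below the bust/thigh baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .corners import DetectorParams
from .geometry import Point3DSet, StereoRig, reverse_rotate, triangulate
from .markers import HSVRanges
from .matching import (
    MatchedPairList,
    extract_centroids,
    nstep,
    run_algorithm1,
    shift_baseline,
)
from .scene import MeasurementSession, azimuth_coverage_deg

__all__ = [
    "GirthResult",
    "MeasurementReport",
    "IncompleteGirdleError",
    "reconstruct_line",
    "fit_girth",
    "select_measurement",
    "mad",
    "measure_session",
]

logger = logging.getLogger(__name__)

BODY_PARTS = ("bust", "under-bust", "waist", "hip", "thigh", "mid-thigh")
# parts measured on a dedicated line two steps below their parent baseline
SHIFTED_PARTS = {"under-bust": "bust", "mid-thigh": "thigh"}


class IncompleteGirdleError(ValueError):
    """Raised when reconstructed points do not wrap around the body."""


@dataclass
class GirthResult:
    """Outcome of one girth measurement."""

    body_part: str
    per_line_cm: dict  # line offset -> circumference (cm)
    selected_cm: float
    per_line_counts: dict = field(default_factory=dict)
    ground_truth_cm: float | None = None

    @property
    def error_cm(self) -> float | None:
        if self.ground_truth_cm is None:
            return None
        return self.selected_cm - self.ground_truth_cm


@dataclass
class MeasurementReport:
    """Proposed vs reference girths over subjects, with MAD per part."""

    body_part: str
    proposed_cm: np.ndarray
    reference_cm: np.ndarray

    def __post_init__(self) -> None:
        self.proposed_cm = np.asarray(self.proposed_cm, dtype=float).ravel()
        self.reference_cm = np.asarray(self.reference_cm, dtype=float).ravel()
        if self.proposed_cm.shape != self.reference_cm.shape:
            raise ValueError("incompatible series")

    @property
    def errors_cm(self) -> np.ndarray:
        return self.proposed_cm - self.reference_cm

    @property
    def error_rates_pct(self) -> np.ndarray:
        return 100.0 * self.errors_cm / self.reference_cm

    @property
    def mad_cm(self) -> float:
        return mad(self.proposed_cm, self.reference_cm)


def reconstruct_line(
    pairs_per_view: list,
    rig: StereoRig,
    angles=None,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
) -> Point3DSet:
    """Triangulate every matched pair and undo each view's turntable rotation.

    ``pairs_per_view`` holds one :class:`MatchedPairList` per view; the
    turntable axis is expressed in the same frame as the triangulated points
    (the left-camera frame for a calibrated rig).  Angles default to each
    pair list's stored angle.
    """
    if len(pairs_per_view) < 1:
        raise ValueError("need at least one view of matched pairs")
    sets = []
    for i, pairs in enumerate(pairs_per_view):
        ang = pairs.angle if angles is None else angles[i]
        pts = []
        for j in range(len(pairs)):
            try:
                pts.append(triangulate(pairs.left_xy[j], pairs.right_xy[j], rig))
            except Exception as exc:
                raise type(exc)(
                    f"view {i} (angle {ang} deg), pair {j}: {exc}"
                ) from exc
        pset = Point3DSet(
            np.array(pts).reshape(-1, 3),
            line_index=np.full(len(pairs), pairs.line_index),
            angle=np.full(len(pairs), ang),
        )
        sets.append(reverse_rotate(pset, ang, axis_point, axis_dir))
    return Point3DSet.concatenate(sets)


def _plane_basis(axis_dir):
    n = np.asarray(axis_dir, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ n) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    return n, e1, np.cross(n, e1)


def fit_girth(
    points: Point3DSet | np.ndarray,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
    min_points: int = 6,
    min_coverage_deg: float = 300.0,
    samples: int = 4096,
) -> float:
    """Circumference (cm) of the closed curve through a girdle of 3-D points.

    Points are projected onto the plane normal to the body axis at their mean
    height, sorted by azimuth about their centroid, and interpolated by a
    periodic cubic spline in cumulative chord length (the intermediate
    parameter); the returned value is the spline's arc length.  Requires at
    least ``min_points`` points spanning ``min_coverage_deg`` of azimuth.
    """
    pts = points.points if isinstance(points, Point3DSet) else np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) < min_points:
        raise IncompleteGirdleError(
            f"incomplete girdle: {len(pts)} points (need >= {min_points})"
        )
    n, e1, e2 = _plane_basis(axis_dir)
    rel = pts - np.asarray(axis_point, dtype=float)
    xy = np.stack([rel @ e1, rel @ e2], axis=-1)

    cov = azimuth_coverage_deg(pts, axis_point, axis_dir)
    if cov < min_coverage_deg:
        raise IncompleteGirdleError(
            f"incomplete girdle: azimuth coverage {cov:.1f} deg "
            f"(need >= {min_coverage_deg})"
        )

    center = xy.mean(axis=0)
    az = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0])
    order = np.argsort(az)
    loop = xy[order]
    # duplicate azimuths (coincident points) would break the spline knots
    keep = np.concatenate([[True], np.linalg.norm(np.diff(loop, axis=0), axis=1) > 1e-12])
    loop = loop[keep]
    closed = np.vstack([loop, loop[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, closed, bc_type="periodic")
    tt = np.linspace(0.0, t[-1], samples + 1)
    dxy = spline(tt, 1)
    speed = np.linalg.norm(dxy, axis=1)
    length = np.trapezoid(speed, tt)
    return float(length * 100.0)


def select_measurement(per_line_girths: dict, body_part: str) -> float:
    """Apply the garment-standard selection rule to per-line girths.

    ``per_line_girths`` maps line offsets (in checkerboard steps from the
    marker baseline) to circumferences.  Bust, hip and thigh report the
    maximum of their three lines; the waist reports the minimum; under-bust
    and mid-thigh report the single line shifted two steps below the parent
    baseline (offset +2, y growing downward).
    """
    if body_part not in BODY_PARTS:
        raise ValueError(f"unknown body part {body_part!r}")
    if body_part in SHIFTED_PARTS:
        if 2 not in per_line_girths:
            raise ValueError(
                "invalid line set: under-bust/mid-thigh need the +2-step line"
            )
        return float(per_line_girths[2])
    if len(per_line_girths) != 3:
        raise ValueError(
            f"invalid line set: expected 3 lines, got {sorted(per_line_girths)}"
        )
    values = [float(v) for v in per_line_girths.values()]
    return min(values) if body_part == "waist" else max(values)


def mad(proposed, reference) -> float:
    """Mean absolute difference between two equal-length series."""
    p = np.asarray(proposed, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.shape != r.shape or len(p) < 1:
        raise ValueError("incompatible series")
    return float(np.mean(np.abs(p - r)))


def measure_session(
    session: MeasurementSession,
    ranges: HSVRanges | None = None,
    detector: DetectorParams | None = None,
    body_part: str | None = None,
    step_px: int | None = None,
    use_masks: bool = True,
) -> GirthResult:
    """Run the full measurement pipeline on a simulated session.

    Per view: extract marker centroids once, detect and refine corners once,
    then match each measurement line by shifting the marker rectangle in
    steps of the checkerboard pixel pitch.  Per line: triangulate, de-rotate
    by the turntable angle, merge views, fit the closed curve.  Finally the
    garment selection rule picks the reported girth.
    """
    from .corners import detect_corners, refine_subpixel

    part = body_part or session.body_part
    if part in SHIFTED_PARTS:
        offsets = (2,)
    else:
        offsets = (-1, 0, 1)
    rig = session.rig
    step = step_px if step_px is not None else nstep(rig.stereo.shooting_distance_D)
    det = detector or DetectorParams()

    pairs_per_line: dict = {off: [] for off in offsets}
    for view in session.views:
        lmask = view.left_mask if use_masks else None
        rmask = view.right_mask if use_masks else None
        base = extract_centroids(view.left_image, view.right_image, ranges, lmask, rmask)
        cl = detect_corners(view.left_image, det, mask=lmask, view="left")
        cr = detect_corners(view.right_image, det, mask=rmask, view="right")
        cl = refine_subpixel(view.left_image, cl, det.refine_window,
                             det.refine_max_iter, det.refine_eps, det.smooth_sigma)
        cr = refine_subpixel(view.right_image, cr, det.refine_window,
                             det.refine_max_iter, det.refine_eps, det.smooth_sigma)
        for off in offsets:
            cents = shift_baseline(base, off, step,
                                   image_height=rig.stereo.left.image_height)
            try:
                pairs = run_algorithm1(
                    view.left_image, view.right_image,
                    centroids=cents, corners_lr=(cl, cr),
                    line_index=off, angle=view.angle,
                )
            except Exception as exc:
                raise type(exc)(
                    f"view {view.pair_index} (angle {view.angle} deg), "
                    f"line {off:+d}: {exc}"
                ) from exc
            pairs_per_line[off].append(pairs)
            logger.debug(
                "view %d line %+d: %d pairs", view.pair_index, off, len(pairs)
            )

    axis_point = rig.axis_point_left
    axis_dir = rig.axis_dir_left
    per_line_cm: dict = {}
    per_line_counts: dict = {}
    for off, pair_lists in pairs_per_line.items():
        pts = reconstruct_line(pair_lists, rig.stereo,
                               axis_point=axis_point, axis_dir=axis_dir)
        per_line_counts[off] = len(pts)
        per_line_cm[off] = fit_girth(pts, axis_point, axis_dir)

    selected = select_measurement(per_line_cm, part)
    return GirthResult(
        body_part=part,
        per_line_cm=per_line_cm,
        selected_cm=selected,
        per_line_counts=per_line_counts,
        ground_truth_cm=session.ground_truth.girth_m * 100.0,
    )
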