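"""Marker-constrained, order-based stereo correspondence of checkerboard
corners.

The matcher restricts each view's corner set to the axis-aligned rectangle
strictly between the red and cyan marker centroids (the regional constraint),
sorts the survivors of both views by ascending x, and pairs them index by
index — on a single checkerboard row the x-order uniquely identifies each
physical corner, so no descriptor matching is needed.  Additional rows are
reached by shifting the marker centroids vertically in steps of the
checkerboard pixel pitch ``n_step``, which is tied to the shooting distance
by a fitted quadratic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corners import CornerSet, DetectorParams, detect_corners, refine_subpixel
from .markers import (
    HSVRanges,
    MarkerCentroids,
    centroid,
    extract_marker_set,
)

__all__ = [
    "ConstraintError",
    "CountMismatchError",
    "ShiftOutOfBoundsError",
    "MatchedPairList",
    "MultilineConfig",
    "regional_constrain",
    "order_and_match",
    "nstep",
    "shift_baseline",
    "run_algorithm1",
]

logger = logging.getLogger(__name__)

# fitted pixel-step polynomial coefficients (pitch vs shooting distance, m)
NSTEP_COEFFS = (7.02, -45.18, 93.43)
NSTEP_VALID_RANGE = (1.5, 3.0)


class ConstraintError(ValueError):
    """Raised when the marker rectangle keeps fewer than two corners."""


class CountMismatchError(ValueError):
    """Raised when the two constrained corner sets differ in cardinality."""


class ShiftOutOfBoundsError(ValueError):
    """Raised when a shifted marker rectangle leaves the image."""


@dataclass
class MatchedPairList:
    """Ordered left/right corner correspondences for one measurement line."""

    left_xy: np.ndarray
    right_xy: np.ndarray
    line_index: int = 0
    angle: float = 0.0

    def __post_init__(self) -> None:
        self.left_xy = np.asarray(self.left_xy, dtype=float).reshape(-1, 2)
        self.right_xy = np.asarray(self.right_xy, dtype=float).reshape(-1, 2)
        if len(self.left_xy) != len(self.right_xy):
            raise CountMismatchError(
                f"count mismatch: {len(self.left_xy)} left vs "
                f"{len(self.right_xy)} right corners"
            )
        for name, xy in (("left", self.left_xy), ("right", self.right_xy)):
            if len(xy) > 1:
                dx = np.diff(xy[:, 0])
                dy = np.diff(xy[:, 1])
                # ascending x; exact ties (impossible on a single corner row)
                # fall back to ascending y so the order stays total
                if not np.all((dx > 0) | ((dx == 0) & (dy > 0))):
                    raise ValueError(
                        f"{name} corners must be strictly increasing in (x, y)"
                    )

    def __len__(self) -> int:
        return len(self.left_xy)


@dataclass(frozen=True)
class MultilineConfig:
    """Multi-line measurement settings: shooting distance, pixel step, offsets."""

    shooting_distance: float = 2.4
    line_offsets: tuple = (-1, 0, 1)

    @property
    def n_step(self) -> int:
        return nstep(self.shooting_distance)


def nstep(distance_m: float) -> int:
    """Checkerboard pixel pitch at shooting distance D (metres).

    Evaluates the fitted quadratic ``7.02 D^2 - 45.18 D + 93.43`` and rounds
    to the nearest integer pixel.  Outside the fitted validity range
    (1.5-3.0 m by default) a warning is logged but the value is returned.
    """
    if distance_m <= 0:
        raise ValueError("shooting distance must be positive")
    lo, hi = NSTEP_VALID_RANGE
    if not lo <= distance_m <= hi:
        logger.warning(
            "shooting distance %.2f m outside the fitted validity range [%g, %g] m",
            distance_m,
            lo,
            hi,
        )
    a, b, c = NSTEP_COEFFS
    return int(round(a * distance_m**2 + b * distance_m + c))


def regional_constrain(
    corners: CornerSet, red: tuple, cyan: tuple
) -> CornerSet:
    """Corners strictly inside the rectangle spanned by the two centroids.

    The bounds use min/max of the red and cyan coordinates, so the result is
    symmetric under swapping the markers.  Corners exactly on the boundary
    are excluded (strict inequalities).  Fewer than two survivors raise
    :class:`ConstraintError`.
    """
    rx, ry = red
    cx, cy = cyan
    if rx == cx or ry == cy:
        raise ValueError("marker centroids must differ in both x and y")
    x_lo, x_hi = min(rx, cx), max(rx, cx)
    y_lo, y_hi = min(ry, cy), max(ry, cy)
    keep = (
        (corners.xs > x_lo)
        & (corners.xs < x_hi)
        & (corners.ys > y_lo)
        & (corners.ys < y_hi)
    )
    n = int(keep.sum())
    if n < 2:
        raise ConstraintError(
            f"constraint too tight: {n} corner(s) inside rectangle "
            f"x=({x_lo:.1f},{x_hi:.1f}) y=({y_lo:.1f},{y_hi:.1f})"
        )
    return CornerSet(
        corners.xs[keep],
        corners.ys[keep],
        corners.responses[keep],
        view=corners.view,
        refined=corners.refined[keep],
    )


def _xsorted(corners: CornerSet) -> np.ndarray:
    # total order: ascending x, ties broken by ascending y
    order = np.lexsort((corners.ys, corners.xs))
    return np.stack([corners.xs[order], corners.ys[order]], axis=-1)


def order_and_match(
    left: CornerSet, right: CornerSet, line_index: int = 0, angle: float = 0.0
) -> MatchedPairList:
    """Pair the i-th left corner with the i-th right corner after x-sort.

    Requires equal cardinality; a mismatch raises :class:`CountMismatchError`
    with per-view diagnostics rather than silently truncating.
    """
    if len(left) != len(right):
        raise CountMismatchError(
            f"count mismatch: {len(left)} left vs {len(right)} right corners"
        )
    return MatchedPairList(
        _xsorted(left), _xsorted(right), line_index=line_index, angle=angle
    )


def shift_baseline(
    centroids: MarkerCentroids,
    offset: int,
    step: int,
    image_height: int | None = None,
) -> MarkerCentroids:
    """Move all four marker centroids by ``offset * step`` pixels along y.

    Mirrors the multi-line scheme: the marker rectangle slides one
    checkerboard row per step while x stays fixed.  When ``image_height`` is
    given, a rectangle leaving the image raises
    :class:`ShiftOutOfBoundsError`.
    """
    dy = float(offset * step)
    shifted = centroids.shifted(dy)
    if image_height is not None:
        ys = [
            shifted.left_red[1],
            shifted.left_cyan[1],
            shifted.right_red[1],
            shifted.right_cyan[1],
        ]
        if min(ys) < 0 or max(ys) > image_height - 1:
            raise ShiftOutOfBoundsError(
                f"shift out of bounds: offset {offset} moves the marker "
                f"rectangle outside the image (y span {min(ys):.1f}..{max(ys):.1f})"
            )
    return shifted


def extract_centroids(
    left_image: np.ndarray,
    right_image: np.ndarray,
    ranges: HSVRanges | None = None,
    left_mask: np.ndarray | None = None,
    right_mask: np.ndarray | None = None,
) -> MarkerCentroids:
    """Red/cyan marker centroids for a stereo pair."""
    lr = centroid(extract_marker_set(left_image, "red", ranges, left_mask))
    lc = centroid(extract_marker_set(left_image, "cyan", ranges, left_mask))
    rr = centroid(extract_marker_set(right_image, "red", ranges, right_mask))
    rc = centroid(extract_marker_set(right_image, "cyan", ranges, right_mask))
    return MarkerCentroids(lr, lc, rr, rc)


def run_algorithm1(
    left_image: np.ndarray,
    right_image: np.ndarray,
    ranges: HSVRanges | None = None,
    detector: DetectorParams | None = None,
    left_mask: np.ndarray | None = None,
    right_mask: np.ndarray | None = None,
    centroids: MarkerCentroids | None = None,
    corners_lr: tuple | None = None,
    line_index: int = 0,
    angle: float = 0.0,
) -> MatchedPairList:
    """The full refined matching procedure on one segmented stereo pair.

    Steps: extract red/cyan marker pixel sets and their centroids in both
    views; detect and sub-pixel-refine the corner sets; apply the marker
    rectangle constraint per view; order each constrained set by x; pair in
    order.  ``centroids``/``corners_lr`` may be supplied to reuse work across
    measurement lines of the same pair.
    """
    if centroids is None:
        centroids = extract_centroids(
            left_image, right_image, ranges, left_mask, right_mask
        )
    if corners_lr is None:
        p = detector or DetectorParams()
        cl = detect_corners(left_image, p, mask=left_mask, view="left")
        cr = detect_corners(right_image, p, mask=right_mask, view="right")
        cl = refine_subpixel(
            left_image, cl, p.refine_window, p.refine_max_iter, p.refine_eps,
            p.smooth_sigma,
        )
        cr = refine_subpixel(
            right_image, cr, p.refine_window, p.refine_max_iter, p.refine_eps,
            p.smooth_sigma,
        )
    else:
        cl, cr = corners_lr
    con_l = regional_constrain(cl, centroids.left_red, centroids.left_cyan)
    con_r = regional_constrain(cr, centroids.right_red, centroids.right_cyan)
    return order_and_match(con_l, con_r, line_index=line_index, angle=angle)
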