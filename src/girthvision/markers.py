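"""HSV colour classification and marker centroid extraction.

The garment carries small red and cyan marker cells whose centroids define
the rectangular regional constraint for stereo matching.  Colours are
classified in HSV with hue on the 0-180 scale and saturation/value on 0-255
(the convention of the reference colour table).  Classification order is
black first (low value dominates), then white, then red (two hue intervals),
then cyan; every bound is configurable.

Intervals are half-open ``[min, max)``; the printed table endpoints are the
defaults.  The table's white value ceiling of 225 is treated as a misprint
for 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "HSVRanges",
    "PixelSet",
    "MarkerCentroids",
    "MarkerNotFoundError",
    "classify_hsv",
    "classify_hsv_image",
    "extract_marker_set",
    "centroid",
    "rgb_to_hsv180",
]

_COLORS = ("red", "cyan", "black", "white")


class MarkerNotFoundError(ValueError):
    """Raised when a required marker colour has no pixels in the image."""


@dataclass(frozen=True)
class HSVRanges:
    """Per-colour HSV windows; red carries two hue intervals.

    Hue in [0, 180], saturation and value in [0, 255].  Defaults follow the
    reference colour table; the text's thresholds (value > 46, saturation >
    43) are the source of the minima.
    """

    red_h1: tuple = (0, 10)
    red_h2: tuple = (156, 180)
    red_s: tuple = (45, 255)
    red_v: tuple = (46, 255)
    cyan_h: tuple = (78, 99)
    cyan_s: tuple = (43, 255)
    cyan_v: tuple = (46, 255)
    black_h: tuple = (0, 180)
    black_s: tuple = (0, 255)
    black_v: tuple = (0, 46)
    white_h: tuple = (0, 180)
    white_s: tuple = (0, 30)
    white_v: tuple = (221, 255)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min exceeds max")


@dataclass
class PixelSet:
    """Member pixel coordinates of one colour in one view.

    ``xs``/``ys`` are integer pixel coordinates; the set is unordered
    (operations on it are order-independent).
    """

    xs: np.ndarray
    ys: np.ndarray
    color: str

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float).ravel()
        self.ys = np.asarray(self.ys, dtype=float).ravel()
        if self.xs.shape != self.ys.shape:
            raise ValueError("xs and ys must have equal length")

    def __len__(self) -> int:
        return len(self.xs)


@dataclass
class MarkerCentroids:
    """Red/cyan marker centroids for the left and right views (pixels)."""

    left_red: tuple
    left_cyan: tuple
    right_red: tuple
    right_cyan: tuple

    def shifted(self, dy: float) -> "MarkerCentroids":
        """All four centroids moved by ``dy`` pixels along y (x unchanged)."""
        mv = lambda c: (c[0], c[1] + dy)
        return MarkerCentroids(
            mv(self.left_red), mv(self.left_cyan), mv(self.right_red), mv(self.right_cyan)
        )


def _in(value, interval, top) -> bool:
    # half-open [lo, hi), closed at the full-scale top so that pure white
    # (V=255) and hue 180 (== hue 0) remain representable
    lo, hi = interval
    if hi >= top:
        return lo <= value <= hi
    return lo <= value < hi


def classify_hsv(h: float, s: float, v: float, ranges: HSVRanges | None = None) -> str:
    """Classify one HSV pixel as red, cyan, black, white or other."""
    if ranges is None:
        ranges = HSVRanges()
    if not (0 <= h <= 180 and 0 <= s <= 255 and 0 <= v <= 255):
        raise ValueError(f"invalid HSV components ({h}, {s}, {v})")
    if (
        _in(h, ranges.black_h, 180)
        and _in(s, ranges.black_s, 255)
        and _in(v, ranges.black_v, 255)
    ):
        return "black"
    if (
        _in(h, ranges.white_h, 180)
        and _in(s, ranges.white_s, 255)
        and _in(v, ranges.white_v, 255)
    ):
        return "white"
    if (
        (_in(h, ranges.red_h1, 180) or _in(h, ranges.red_h2, 180))
        and _in(s, ranges.red_s, 255)
        and _in(v, ranges.red_v, 255)
    ):
        return "red"
    if (
        _in(h, ranges.cyan_h, 180)
        and _in(s, ranges.cyan_s, 255)
        and _in(v, ranges.cyan_v, 255)
    ):
        return "cyan"
    return "other"


def rgb_to_hsv180(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV with H in [0,180], S,V in [0,255]."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    hsv = rgb2hsv(img.astype(float) / 255.0)
    out = np.empty_like(hsv)
    out[..., 0] = hsv[..., 0] * 180.0
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def _mask_interval(channel, interval, top):
    lo, hi = interval
    if hi >= top:
        return (channel >= lo) & (channel <= hi)
    return (channel >= lo) & (channel < hi)


def classify_hsv_image(image: np.ndarray, ranges: HSVRanges | None = None) -> np.ndarray:
    """Vectorised classification of a full RGB image.

    Returns an array of dtype ``<U5`` with values in
    {red, cyan, black, white, other}, honouring the same precedence as
    :func:`classify_hsv`.
    """
    if ranges is None:
        ranges = HSVRanges()
    hsv = rgb_to_hsv180(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    labels = np.full(h.shape, "other", dtype="<U5")

    def window(hint, sint, vint):
        return (
            _mask_interval(h, hint, 180)
            & _mask_interval(s, sint, 255)
            & _mask_interval(v, vint, 255)
        )

    red = (
        (_mask_interval(h, ranges.red_h1, 180) | _mask_interval(h, ranges.red_h2, 180))
        & _mask_interval(s, ranges.red_s, 255)
        & _mask_interval(v, ranges.red_v, 255)
    )
    cyan = window(ranges.cyan_h, ranges.cyan_s, ranges.cyan_v)
    white = window(ranges.white_h, ranges.white_s, ranges.white_v)
    black = window(ranges.black_h, ranges.black_s, ranges.black_v)
    labels[cyan] = "cyan"
    labels[red] = "red"
    labels[white] = "white"
    labels[black] = "black"  # black tested first == highest precedence
    return labels


def extract_marker_set(
    image: np.ndarray,
    color: str,
    ranges: HSVRanges | None = None,
    mask: np.ndarray | None = None,
    largest_blob: bool = True,
) -> PixelSet:
    """Extract the pixel set of one marker colour from an RGB image.

    When ``largest_blob`` is set (default) only the largest 8-connected
    component is kept, guarding against stray pixels of the same colour.
    Raises :class:`MarkerNotFoundError` when no pixel matches.
    """
    if color not in ("red", "cyan", "black", "white"):
        raise ValueError(f"unknown marker colour {color!r}")
    labels = classify_hsv_image(image, ranges)
    hit = labels == color
    if mask is not None:
        hit &= np.asarray(mask).astype(bool)
    if not hit.any():
        raise MarkerNotFoundError(f"marker not found: no {color} pixels")
    if largest_blob:
        lab, n = ndimage.label(hit, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(hit, lab, index=np.arange(1, n + 1))
            hit = lab == (1 + int(np.argmax(sizes)))
    ys, xs = np.nonzero(hit)
    return PixelSet(xs=xs, ys=ys, color=color)


def centroid(pixel_set: PixelSet) -> tuple:
    """Arithmetic-mean centre of a marker pixel set, continuous-valued."""
    if len(pixel_set) == 0:
        raise ValueError("empty pixel set")
    return (float(np.mean(pixel_set.xs)), float(np.mean(pixel_set.ys)))
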