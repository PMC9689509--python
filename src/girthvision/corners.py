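"""Shi-Tomasi corner detection with non-maximum suppression and sub-pixel
refinement.

The detector scores every pixel by the minimum eigenvalue of the local
gradient structure tensor (the Shi-Tomasi criterion), greedily keeps response
maxima separated by a suppression radius, and then relocates each corner to
sub-pixel precision with the classical gradient-orthogonality iteration: the
refined position ``q`` minimises ``sum_p (grad I(p) . (p - q))^2`` over a
window around the corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "CornerSet",
    "DetectorParams",
    "shi_tomasi_response",
    "detect_corners",
    "refine_subpixel",
]


@dataclass
class CornerSet:
    """Detected corners of one view: continuous coordinates + responses."""

    xs: np.ndarray
    ys: np.ndarray
    responses: np.ndarray
    view: str = "left"
    refined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float).ravel()
        self.ys = np.asarray(self.ys, dtype=float).ravel()
        self.responses = np.asarray(self.responses, dtype=float).ravel()
        if not (len(self.xs) == len(self.ys) == len(self.responses)):
            raise ValueError("coordinate and response arrays must align")
        if self.refined is None:
            self.refined = np.zeros(len(self.xs), dtype=bool)
        else:
            self.refined = np.asarray(self.refined, dtype=bool).ravel()

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def xy(self) -> np.ndarray:
        return np.stack([self.xs, self.ys], axis=-1)


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector settings (pixels unless noted).

    ``min_distance`` should sit near half the checkerboard pixel pitch so at
    most one detection survives per physical corner.
    """

    smooth_sigma: float = 1.0
    window_size: int = 5
    quality: float = 0.05
    min_distance: float = 12.0
    refine_window: int = 7
    refine_max_iter: int = 40
    refine_eps: float = 1e-3
    mask_erosion: int = 3
    border: int | None = None  # None: window_size//2 + 3*smooth_sigma


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def _gradients(image: np.ndarray, sigma: float):
    img = _as_gray(image)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma, mode="nearest")
    gy, gx = np.gradient(img)
    return gx, gy


def shi_tomasi_response(
    image: np.ndarray, window_size: int = 5, sigma: float = 1.0
) -> np.ndarray:
    """Per-pixel min-eigenvalue of the smoothed gradient structure tensor."""
    img = _as_gray(image)
    if window_size % 2 != 1 or window_size < 1:
        raise ValueError("window_size must be odd and positive")
    if window_size > min(img.shape):
        raise ValueError("invalid window: larger than image")
    gx, gy = _gradients(img, sigma)
    jxx = ndimage.uniform_filter(gx * gx, window_size, mode="nearest")
    jyy = ndimage.uniform_filter(gy * gy, window_size, mode="nearest")
    jxy = ndimage.uniform_filter(gx * gy, window_size, mode="nearest")
    tr_half = 0.5 * (jxx + jyy)
    disc = np.sqrt(np.maximum(0.25 * (jxx - jyy) ** 2 + jxy * jxy, 0.0))
    return tr_half - disc  # min eigenvalue


def detect_corners(
    image: np.ndarray,
    params: DetectorParams | None = None,
    mask: np.ndarray | None = None,
    view: str = "left",
) -> CornerSet:
    """Greedy selection of Shi-Tomasi response maxima.

    Keeps local maxima above ``quality * max(response)``, strongest first,
    suppressing any candidate within ``min_distance`` of an accepted corner.
    When a mask is supplied it is first eroded by ``mask_erosion`` pixels to
    keep silhouette-edge responses out, and detections are restricted to it.
    An empty result is returned (not raised) when nothing passes.
    """
    p = params or DetectorParams()
    if not 0 < p.quality < 1:
        raise ValueError("quality must lie in (0, 1)")
    if p.min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    resp = shi_tomasi_response(image, p.window_size, p.smooth_sigma)

    if mask is not None:
        m = np.asarray(mask).astype(bool)
        if p.mask_erosion > 0:
            m = ndimage.binary_erosion(m, iterations=p.mask_erosion)
        resp = np.where(m, resp, 0.0)

    # image-border responses are artefacts of the edge padding
    border = p.border
    if border is None:
        border = p.window_size // 2 + max(1, int(round(3 * p.smooth_sigma)))
    if border > 0:
        resp[:border, :] = 0.0
        resp[-border:, :] = 0.0
        resp[:, :border] = 0.0
        resp[:, -border:] = 0.0

    peak = float(resp.max())
    if peak <= 0:
        return CornerSet(np.empty(0), np.empty(0), np.empty(0), view=view)
    thresh = p.quality * peak
    local_max = resp == ndimage.maximum_filter(resp, size=3, mode="nearest")
    cand = np.nonzero(local_max & (resp > thresh))
    order = np.argsort(resp[cand])[::-1]
    cy, cx = cand[0][order], cand[1][order]
    cr = resp[cand][order]

    kept_x: list[float] = []
    kept_y: list[float] = []
    kept_r: list[float] = []
    min_d2 = p.min_distance**2
    for x, y, r in zip(cx, cy, cr):
        ok = True
        for kx, ky in zip(kept_x, kept_y):
            if (x - kx) ** 2 + (y - ky) ** 2 < min_d2:
                ok = False
                break
        if ok:
            kept_x.append(float(x))
            kept_y.append(float(y))
            kept_r.append(float(r))
    return CornerSet(np.array(kept_x), np.array(kept_y), np.array(kept_r), view=view)


def refine_subpixel(
    image: np.ndarray,
    corners: CornerSet,
    window: int = 5,
    max_iter: int = 40,
    eps: float = 1e-3,
    smooth_sigma: float = 1.0,
) -> CornerSet:
    """Relocate corners to sub-pixel positions by gradient orthogonality.

    At the true corner the image gradient at every window pixel is orthogonal
    to the displacement from the corner, so ``q`` solves the normal equations
    ``(sum g g^T) q = sum (g g^T) p``.  The window follows the moving
    estimate; gradients are sampled bilinearly.  Corners whose normal matrix
    is singular, or that sit too close to the border, keep their integer
    position and are flagged unrefined.  No corner moves farther than half a
    window from its start.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    gx, gy = _gradients(image, smooth_sigma)
    h, w = gx.shape
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    # Gaussian weighting de-emphasises window edges, as is standard practice
    ww = np.exp(-(ox**2 + oy**2) / (2 * (0.5 * half + 0.5) ** 2))

    new_x = corners.xs.copy()
    new_y = corners.ys.copy()
    refined = np.zeros(len(corners), dtype=bool)

    def sample(grid, px, py):
        x0 = np.floor(px).astype(int)
        y0 = np.floor(py).astype(int)
        fx, fy = px - x0, py - y0
        x1 = np.clip(x0 + 1, 0, w - 1)
        y1 = np.clip(y0 + 1, 0, h - 1)
        x0 = np.clip(x0, 0, w - 1)
        y0 = np.clip(y0, 0, h - 1)
        return (
            grid[y0, x0] * (1 - fx) * (1 - fy)
            + grid[y0, x1] * fx * (1 - fy)
            + grid[y1, x0] * (1 - fx) * fy
            + grid[y1, x1] * fx * fy
        )

    for i in range(len(corners)):
        q = np.array([corners.xs[i], corners.ys[i]])
        start = q.copy()
        if not (half + 1 <= q[0] < w - half - 1 and half + 1 <= q[1] < h - half - 1):
            continue  # too close to the border to refine
        ok = False
        for _ in range(max_iter):
            px = q[0] + ox
            py = q[1] + oy
            sgx = sample(gx, px, py) * ww
            sgy = sample(gy, px, py) * ww
            gxx = np.sum(sgx * sgx)
            gyy = np.sum(sgy * sgy)
            gxy = np.sum(sgx * sgy)
            A = np.array([[gxx, gxy], [gxy, gyy]])
            if np.linalg.cond(A) > 1e12 or np.linalg.det(A) <= 0:
                break  # singular normal matrix: keep integer position
            bx = np.sum((sgx * sgx) * px + (sgx * sgy) * py)
            by = np.sum((sgx * sgy) * px + (sgy * sgy) * py)
            q_new = np.linalg.solve(A, np.array([bx, by]))
            shift = np.linalg.norm(q_new - q)
            if np.linalg.norm(q_new - start) > half:
                q_new = start + (q_new - start) * (half / np.linalg.norm(q_new - start))
            q = q_new
            ok = True
            if shift < eps:
                break
        if ok:
            new_x[i], new_y[i] = q
            refined[i] = True
    return replace(corners, xs=new_x, ys=new_y, refined=refined)
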