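"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express convolutional segmentation networks:
a :class:`Tensor` wrapping a float32 numpy array, and a small set of
differentiable operations (elementwise arithmetic, matmul, im2col-based 2-D
convolution with groups, pooling, bilinear upsampling, concatenation and the
usual activations).  Graphs are only recorded when an input requires
gradients, so pure inference runs at plain-numpy cost.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True

    def __exit__(self, *exc):
        _NoGrad._active = self.prev


def no_grad() -> _NoGrad:
    return _NoGrad()


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting in the backward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad and not _NoGrad._active
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        track = any(p.requires_grad for p in parents) and not _NoGrad._active
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(np.float32)
        else:
            self.grad = self.grad + grad

    # -- basic ops ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _sum_to_shape(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        denom = self.data.size / out_data.size

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape) / denom)

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def max_over(self, axis: int, keepdims: bool = False):
        """Maximum along one axis (gradient flows to the arg-max entries)."""
        out_data = self.data.max(axis=axis, keepdims=True)
        hit = self.data == out_data
        hit = hit / hit.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(hit * gg)

        data = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(data, (self,), backward)

    def relu(self):
        pos = self.data > 0
        out_data = self.data * pos

        def backward(g):
            if self.requires_grad:
                self._accum(g * pos)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -- structured ops ----------------------------------------------------

    def batch_norm(self, gamma: "Tensor", beta: "Tensor",
                   mean: np.ndarray, var: np.ndarray,
                   eps: float = 1e-5, batch_stats: bool = True) -> "Tensor":
        """Fused (N, C, H, W) normalisation: ``gamma * (x - mean)/std + beta``.

        With ``batch_stats`` the gradient accounts for the dependence of the
        batch mean/variance on the input (training mode); otherwise the
        statistics are treated as constants (inference with running stats).
        """
        x = self
        gamma = Tensor._wrap(gamma)
        beta = Tensor._wrap(beta)
        c = x.data.shape[1]
        mu = mean.reshape(1, c, 1, 1).astype(np.float32)
        invstd = (1.0 / np.sqrt(var + eps)).reshape(1, c, 1, 1).astype(np.float32)
        xhat = (x.data - mu) * invstd
        out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

        def backward(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data.reshape(1, c, 1, 1)
                if batch_stats:
                    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                    s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    x._accum(invstd / m * (m * dxhat - s1 - xhat * s2))
                else:
                    x._accum(dxhat * invstd)

        return Tensor._make(out, (x, gamma, beta), backward)

    @staticmethod
    def concat(tensors: list, axis: int = 1) -> "Tensor":
        arrays = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in arrays], axis=axis)
        sizes = [t.data.shape[axis] for t in arrays]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(arrays, parts):
                if t.requires_grad:
                    t._accum(p)

        return Tensor._make(out_data, tuple(arrays), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1) -> "Tensor":
        """2-D convolution, NCHW layout, via im2col matrix multiplication."""
        x, w = self, Tensor._wrap(weight)
        N, C, H, W = x.data.shape
        Cout, Cin_g, kh, kw = w.data.shape
        if C % groups or Cout % groups or Cin_g != C // groups:
            raise ValueError("invalid groups for channel counts")
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1
        cpg_in = C // groups
        cpg_out = Cout // groups

        pointwise = kh == 1 and kw == 1 and stride == 1 and padding == 0
        if pointwise:
            cols = x.data.reshape(N, C, H * W)
        else:
            xp = np.pad(x.data,
                        ((0, 0), (0, 0), (padding, padding), (padding, padding)))
            cols = _im2col(xp, kh, kw, stride, Ho, Wo)  # (N, C*kh*kw, Ho*Wo)

        # (N, g, K, P) x (g, Cout/g, K) -> (N, g, Cout/g, P), batched over g
        cols_g = cols.reshape(N, groups, cpg_in * kh * kw, Ho * Wo)
        wmat = w.data.reshape(groups, cpg_out, Cin_g * kh * kw)
        out = np.matmul(wmat[None], cols_g).reshape(N, Cout, Ho, Wo)
        if bias is not None:
            out = out + Tensor._wrap(bias).data.reshape(1, Cout, 1, 1)

        b = Tensor._wrap(bias) if bias is not None else None

        def backward(g):
            gmat = g.reshape(N, groups, cpg_out, Ho * Wo)
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=(0, 3)).reshape(Cout))
            if w.requires_grad:
                gw = np.matmul(gmat, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.transpose(0, 2, 1)[None], gmat)
                gcols = gcols.reshape(N, C * kh * kw, Ho * Wo)
                if pointwise:
                    x._accum(gcols.reshape(N, C, H, W))
                else:
                    gx = _col2im(
                        gcols,
                        (N, C, H + 2 * padding, W + 2 * padding),
                        kh, kw, stride, Ho, Wo,
                    )
                    if padding:
                        gx = gx[:, :, padding:-padding, padding:-padding]
                    x._accum(gx)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, backward)

    def maxpool2d(self, kernel: int = 2, stride: int | None = None,
                  padding: int = 0) -> "Tensor":
        stride = stride or kernel
        N, C, H, W = self.data.shape
        Ho = (H + 2 * padding - kernel) // stride + 1
        Wo = (W + 2 * padding - kernel) // stride + 1
        xp = np.pad(
            self.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
        cols = _im2col(xp[:, :, None].reshape(N * C, 1, *xp.shape[2:]),
                       kernel, kernel, stride, Ho, Wo)
        cols = cols.reshape(N, C, kernel * kernel, Ho * Wo)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        out = out.reshape(N, C, Ho, Wo)

        def backward(g):
            if not self.requires_grad:
                return
            gcols = np.zeros((N, C, kernel * kernel, Ho * Wo), dtype=np.float32)
            np.put_along_axis(
                gcols, arg[:, :, None], g.reshape(N, C, 1, Ho * Wo), axis=2
            )
            gx = _col2im(
                gcols.reshape(N * C, kernel * kernel, Ho * Wo),
                (N * C, 1, H + 2 * padding, W + 2 * padding),
                kernel, kernel, stride, Ho, Wo,
            ).reshape(N, C, H + 2 * padding, W + 2 * padding)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accum(gx)

        return Tensor._make(out, (self,), backward)

    def adaptive_avg_pool2d(self, out_hw: tuple) -> "Tensor":
        """Average pooling to a target spatial size with torch-style bins."""
        N, C, H, W = self.data.shape
        oh, ow = out_hw
        ys = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
        xs = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
        out = np.empty((N, C, oh, ow), dtype=np.float32)
        for i, (y0, y1) in enumerate(ys):
            for j, (x0, x1) in enumerate(xs):
                out[:, :, i, j] = self.data[:, :, y0:y1, x0:x1].mean(axis=(2, 3))

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            for i, (y0, y1) in enumerate(ys):
                for j, (x0, x1) in enumerate(xs):
                    area = (y1 - y0) * (x1 - x0)
                    gx[:, :, y0:y1, x0:x1] += g[:, :, i, j][:, :, None, None] / area
            self._accum(gx)

        return Tensor._make(out, (self,), backward)

    def upsample_bilinear(self, out_hw: tuple) -> "Tensor":
        """Bilinear resize (align_corners=False convention)."""
        N, C, H, W = self.data.shape
        oh, ow = out_hw
        wy, iy0, iy1 = _linear_weights(H, oh)
        wx, ix0, ix1 = _linear_weights(W, ow)

        def interp(arr):
            rows = arr[:, :, iy0, :] * (1 - wy)[None, None, :, None] + \
                   arr[:, :, iy1, :] * wy[None, None, :, None]
            return rows[:, :, :, ix0] * (1 - wx)[None, None, None, :] + \
                   rows[:, :, :, ix1] * wx[None, None, None, :]

        out = interp(self.data)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            grows = np.zeros((N, C, H, ow), dtype=np.float32)
            np.add.at(grows, (slice(None), slice(None), iy0),
                      g * (1 - wy)[None, None, :, None])
            np.add.at(grows, (slice(None), slice(None), iy1),
                      g * wy[None, None, :, None])
            np.add.at(gx.transpose(0, 1, 3, 2), (slice(None), slice(None), ix0),
                      grows.transpose(0, 1, 3, 2) * (1 - wx)[None, None, :, None])
            np.add.at(gx.transpose(0, 1, 3, 2), (slice(None), slice(None), ix1),
                      grows.transpose(0, 1, 3, 2) * wx[None, None, :, None])
            self._accum(gx)

        return Tensor._make(out, (self,), backward)


def _linear_weights(size_in: int, size_out: int):
    if size_out == 1:
        return np.zeros(1, np.float32), np.zeros(1, int), np.zeros(1, int)
    pos = (np.arange(size_out) + 0.5) * size_in / size_out - 0.5
    pos = np.clip(pos, 0, size_in - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, size_in - 1)
    return (pos - i0).astype(np.float32), i0, i1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    """(N, C, H, W) -> (N, C*kh*kw, ho*wo) patch matrix."""
    N, C, H, W = x.shape
    s0, s1, s2, s3 = x.strides
    shape = (N, C, kh, kw, ho, wo)
    strides = (s0, s1, s2, s3, s2 * stride, s3 * stride)
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(patches).reshape(N, C * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    N, C, H, W = x_shape
    out = np.zeros(x_shape, dtype=np.float32)
    cols = cols.reshape(N, C, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return out
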