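"""Convolutional block attention: sequential channel and spatial gating.

Channel attention squeezes the feature map by global average and max
pooling, passes both pooled vectors through one shared two-layer bias-free
perceptron (reduction ratio r), adds them element-wise and applies a
sigmoid; the resulting per-channel weights rescale the input.  Spatial
attention then concatenates the channel-wise mean and max maps, convolves
them with a single 7x7 kernel and gates every channel by the sigmoid of the
result.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .modules import Conv2d, Linear, Module, ReLU, Sequential

__all__ = ["ChannelAttention", "SpatialAttention", "CBAM",
           "channel_attention", "spatial_attention"]


class ChannelAttention(Module):
    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"invalid reduction: {reduction} does not divide {channels} channels"
            )
        self.channels = channels
        self.reduction = reduction
        self.mlp = Sequential(
            Linear(channels, channels // reduction, bias=False, rng=rng),
            ReLU(),
            Linear(channels // reduction, channels, bias=False, rng=rng),
        )

    def attention(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3)).reshape(n, c)
        mx = x.max_over(3).max_over(2).reshape(n, c)
        return (self.mlp(avg) + self.mlp(mx)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        a = self.attention(x)
        n, c = a.shape
        return x * a.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2,
                           bias=False, rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max_over(1, keepdims=True)
        return self.conv(Tensor.concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


class CBAM(Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels: int, reduction: int = 16,
                 spatial_kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


def channel_attention(feature_map: np.ndarray, reduction: int = 16,
                      module: ChannelAttention | None = None):
    """Functional channel attention on a (C, H, W) or (N, C, H, W) array.

    Returns ``(attention_map, refined_map)`` as numpy arrays; a fresh
    randomly initialised module is used unless one is supplied.
    """
    x = np.asarray(feature_map, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    mod = module or ChannelAttention(x.shape[1], reduction)
    t = Tensor(x)
    a = mod.attention(t)
    out = t * a.reshape(a.shape[0], a.shape[1], 1, 1)
    a_np, out_np = a.data, out.data
    if squeeze:
        a_np, out_np = a_np[0], out_np[0]
    return a_np, out_np


def spatial_attention(feature_map: np.ndarray,
                      module: SpatialAttention | None = None):
    """Functional spatial attention; returns ``(attention_map, refined_map)``."""
    x = np.asarray(feature_map, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    mod = module or SpatialAttention()
    t = Tensor(x)
    a = mod.attention(t)
    out = t * a
    a_np, out_np = a.data, out.data
    if squeeze:
        a_np, out_np = a_np[0], out_np[0]
    return a_np, out_np
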