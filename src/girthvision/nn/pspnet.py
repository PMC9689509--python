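"""Pyramid-pooling segmentation head over the backbone features.

Stage-4 features are average-pooled to four pyramid levels (1x1, 2x2, 3x3
and 6x6 by default), each level is reduced by a 1x1 convolution, upsampled
back bilinearly and concatenated with the input features; a final 3x3
convolution and 1x1 classifier produce per-pixel class scores, upsampled to
the input resolution.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .modules import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
)
from .resnet import ResNetBackbone

__all__ = ["PyramidPooling", "PSPNet", "build_pspnet"]


class PyramidPooling(Module):
    def __init__(self, in_channels: int, pool_sizes=(1, 2, 3, 6),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.pool_sizes = tuple(pool_sizes)
        branch_ch = in_channels // len(self.pool_sizes)
        self.branches = []
        for i, size in enumerate(self.pool_sizes):
            branch = Sequential(
                AdaptiveAvgPool2d(size),
                Conv2d(in_channels, branch_ch, 1, rng=rng),
                BatchNorm2d(branch_ch),
                ReLU(),
            )
            setattr(self, f"branch{i}", branch)
            self.branches.append(branch)
        self.out_channels = in_channels + branch_ch * len(self.pool_sizes)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        feats = [x]
        for branch in self.branches:
            feats.append(branch(x).upsample_bilinear((h, w)))
        return Tensor.concat(feats, axis=1)


class PSPNet(Module):
    """Backbone + pyramid pooling + per-pixel classifier at input resolution."""

    def __init__(self, backbone: ResNetBackbone, num_classes: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.backbone = backbone
        self.ppm = PyramidPooling(backbone.out_channels,
                                  backbone.config.pool_sizes, rng=rng)
        head_ch = max(64, backbone.out_channels // 4)
        self.head = Sequential(
            Conv2d(self.ppm.out_channels, head_ch, 3, padding=1, rng=rng),
            BatchNorm2d(head_ch),
            ReLU(),
            Conv2d(head_ch, num_classes, 1, bias=True, rng=rng),
        )
        self.num_classes = num_classes

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        feats = self.backbone(x)
        scores = self.head(self.ppm(feats))
        return scores.upsample_bilinear((h, w))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class-index masks for a batch of (N, 3, H, W) images (no grad)."""
        from .autograd import no_grad

        self.eval()
        with no_grad():
            scores = self.forward(Tensor(np.asarray(images, dtype=np.float32)))
        return np.argmax(scores.data, axis=1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over the class axis)."""
        from .autograd import no_grad

        self.eval()
        with no_grad():
            scores = self.forward(Tensor(np.asarray(images, dtype=np.float32))).data
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def build_pspnet(backbone: ResNetBackbone, num_classes: int,
                 rng: np.random.Generator | None = None) -> PSPNet:
    return PSPNet(backbone, num_classes, rng=rng)
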