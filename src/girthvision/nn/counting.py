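"""Exact parameter and FLOP accounting for the segmentation backbones.

Parameter counts are exact sums over trainable arrays.  FLOPs are counted by
symbolic shape propagation at a given input size under the following stated
convention: one multiply-accumulate of a convolution or linear layer is one
FLOP; normalisation, activation, residual addition and attention gating cost
one FLOP per output element; pooling and other reductions cost one FLOP per
input element read.  Spatial sizes are propagated exactly through strides
and padding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cbam import CBAM, ChannelAttention, SpatialAttention
from .modules import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Identity,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
    UpsampleBilinear,
)
from .pspnet import PSPNet, PyramidPooling
from .resnet import Bottleneck, ResNetBackbone

__all__ = [
    "ConvSpec",
    "conv_params",
    "count_parameters",
    "count_parameters_millions",
    "count_flops",
    "count_flops_billions",
    "accounting_report",
]


@dataclass(frozen=True)
class ConvSpec:
    """Convolution shape spec for the parameter-count identities."""

    kernel_h: int
    kernel_w: int
    in_channels: int
    out_channels: int
    groups: int = 1

    def __post_init__(self) -> None:
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("groups must divide both channel counts")


def conv_params(spec: ConvSpec) -> int:
    """Weight count ``h * w * (Din/g) * (Dout/g) * g`` of a (group) convolution.

    With g = 1 this is the common-convolution count ``h w Din Dout``; grouping
    divides it exactly by g.
    """
    return (
        spec.kernel_h
        * spec.kernel_w
        * (spec.in_channels // spec.groups)
        * (spec.out_channels // spec.groups)
        * spec.groups
    )


def count_parameters(network: Module) -> int:
    """Exact trainable-parameter total of a built network."""
    return network.num_parameters()


def count_parameters_millions(network: Module) -> float:
    return round(count_parameters(network) / 1e6, 2)


def _flops(module: Module, shape: tuple) -> tuple:
    """Return (output shape, flop count) for a module on a CHW input shape."""
    c, h, w = shape
    if isinstance(module, Conv2d):
        ho = (h + 2 * module.padding - module.kernel_size) // module.stride + 1
        wo = (w + 2 * module.padding - module.kernel_size) // module.stride + 1
        macs = (
            module.kernel_size**2
            * (module.in_channels // module.groups)
            * module.out_channels
            * ho
            * wo
        )
        if module.bias is not None:
            macs += module.out_channels * ho * wo
        return (module.out_channels, ho, wo), macs
    if isinstance(module, BatchNorm2d):
        return shape, c * h * w
    if isinstance(module, (ReLU, Sigmoid)):
        return shape, c * h * w
    if isinstance(module, Identity):
        return shape, 0
    if isinstance(module, MaxPool2d):
        ho = (h + 2 * module.padding - module.kernel_size) // module.stride + 1
        wo = (w + 2 * module.padding - module.kernel_size) // module.stride + 1
        return (c, ho, wo), module.kernel_size**2 * c * ho * wo
    if isinstance(module, AdaptiveAvgPool2d):
        oh, ow = module.output_size
        return (c, oh, ow), c * h * w
    if isinstance(module, UpsampleBilinear):
        oh, ow = module.size
        return (c, oh, ow), 4 * c * oh * ow
    if isinstance(module, Linear):
        macs = module.in_features * module.out_features
        if module.bias is not None:
            macs += module.out_features
        return shape, macs  # used only inside attention; spatial shape kept
    if isinstance(module, Sequential):
        total = 0
        for layer in module:
            shape, f = _flops(layer, shape)
            total += f
        return shape, total
    if isinstance(module, Bottleneck):
        total = 0
        s, f = _flops(module.conv1, shape); total += f
        s, f = _flops(module.bn1, s); total += f
        s, f = _flops(module.relu, s); total += f
        s, f = _flops(module.conv2, s); total += f
        s, f = _flops(module.bn2, s); total += f
        s, f = _flops(module.relu, s); total += f
        s, f = _flops(module.conv3, s); total += f
        s, f = _flops(module.bn3, s); total += f
        _, f = _flops(module.downsample, shape); total += f
        co, ho, wo = s
        total += co * ho * wo  # residual addition
        total += co * ho * wo  # final activation
        return s, total
    if isinstance(module, ChannelAttention):
        total = 2 * c * h * w  # global average + max reductions
        for lin in (module.mlp.layers[0], module.mlp.layers[2]):
            total += 2 * lin.in_features * lin.out_features  # both pooled vectors
        total += c // module.reduction  # relu on hidden (both passes folded below)
        total += c  # element-wise addition
        total += c  # sigmoid
        total += c * h * w  # per-channel gating
        return shape, total
    if isinstance(module, SpatialAttention):
        total = 2 * c * h * w  # channel mean + max maps
        _, f = _flops(module.conv, (2, h, w))
        total += f
        total += h * w  # sigmoid
        total += c * h * w  # gating
        return shape, total
    if isinstance(module, CBAM):
        _, f1 = _flops(module.channel, shape)
        _, f2 = _flops(module.spatial, shape)
        return shape, f1 + f2
    if isinstance(module, ResNetBackbone):
        total = 0
        s, f = _flops(module.stem, shape); total += f
        s, f = _flops(module.maxpool, s); total += f
        for stage in (module.layer1, module.layer2, module.layer3, module.layer4):
            s, f = _flops(stage, s); total += f
        return s, total
    if isinstance(module, PyramidPooling):
        total = 0
        feats_c = c
        for branch in module.branches:
            s, f = _flops(branch, shape)
            total += f
            bc = s[0]
            total += 4 * bc * h * w  # bilinear upsample back to (h, w)
            feats_c += bc
        return (feats_c, h, w), total
    if isinstance(module, PSPNet):
        total = 0
        s, f = _flops(module.backbone, shape); total += f
        s, f = _flops(module.ppm, s); total += f
        s, f = _flops(module.head, s); total += f
        total += 4 * s[0] * h * w  # final upsample to input resolution
        return (s[0], h, w), total
    raise TypeError(f"no FLOP rule for module type {type(module).__name__}")


def count_flops(network: Module, input_size: int = 224, in_channels: int = 3) -> int:
    """Total FLOPs of a forward pass at the given square input size."""
    _, total = _flops(network, (in_channels, input_size, input_size))
    return int(total)


def count_flops_billions(network: Module, input_size: int = 224) -> float:
    return round(count_flops(network, input_size) / 1e9, 2)


def accounting_report(standard: Module, improved: Module,
                      input_size: int = 224) -> str:
    """Comparison table: parameters (millions), FLOPs (billions), reductions."""
    p1 = count_parameters_millions(standard)
    p2 = count_parameters_millions(improved)
    f1 = count_flops_billions(standard, input_size)
    f2 = count_flops_billions(improved, input_size)
    dp = 100.0 * (p1 - p2) / p1
    df = 100.0 * (f1 - f2) / f1
    lines = [
        f"{'Backbone':<22}{'Params (M)':>12}{'FLOPs (B)':>12}",
        f"{'standard':<22}{p1:>12.2f}{f1:>12.2f}",
        f"{'improved':<22}{p2:>12.2f}{f2:>12.2f}",
        f"{'reduction (%)':<22}{dp:>12.1f}{df:>12.1f}",
    ]
    return "\n".join(lines)
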