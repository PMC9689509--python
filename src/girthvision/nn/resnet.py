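"""ResNet101-topology feature extractor with grouped bottlenecks and
optional attention blocks after each stage.

The backbone is the standard deep residual network: a 7x7/64 stride-2 stem,
3x3 stride-2 max pooling, then four stages of bottleneck blocks with
(3, 4, 23, 3) blocks and (256, 512, 1024, 2048) output channels.  Two
efficiency/accuracy modifications are supported: the 3x3 convolution of
every bottleneck may be a group convolution (g groups divides its parameter
and multiply count by g), and a channel+spatial attention block may be
appended to each stage's output.  No classification head is attached — the
backbone ends at the stage-4 feature map (1/32 resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cbam import CBAM
from .modules import (
    BatchNorm2d,
    Conv2d,
    Identity,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = ["BackboneConfig", "Bottleneck", "ResNetBackbone", "build_backbone"]

RESNET101_BLOCKS = (3, 4, 23, 3)


@dataclass(frozen=True)
class BackboneConfig:
    """Backbone hyper-parameters.

    ``groups`` applies to every bottleneck's 3x3 convolution; ``cbam_enabled``
    inserts an attention block after each of the four stages with reduction
    ratio ``cbam_reduction``.  Block counts and pyramid pool sizes default to
    the ResNet101 / four-level pyramid layout.
    """

    groups: int = 1
    cbam_enabled: bool = False
    cbam_reduction: int = 16
    blocks: tuple = RESNET101_BLOCKS
    pool_sizes: tuple = (1, 2, 3, 6)
    # reduced-depth/-stride variants for desk-scale experiments
    reduced_channels: int | None = None
    stem_stride: int = 2
    use_maxpool: bool = True
    stage_strides: tuple = (1, 2, 2, 2)

    def __post_init__(self) -> None:
        if self.groups < 1:
            raise ValueError("invalid groups")
        if self.cbam_reduction < 1:
            raise ValueError("invalid reduction")


class Bottleneck(Module):
    """1x1 reduce -> 3x3 (grouped) -> 1x1 expand, with identity shortcut."""

    expansion = 4

    def __init__(self, in_channels: int, mid_channels: int, stride: int = 1,
                 groups: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        out_channels = mid_channels * self.expansion
        if mid_channels % groups:
            raise ValueError(
                f"invalid groups: {groups} does not divide width {mid_channels}"
            )
        self.conv1 = Conv2d(in_channels, mid_channels, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid_channels)
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, stride=stride,
                            padding=1, groups=groups, rng=rng)
        self.bn2 = BatchNorm2d(mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.relu = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.downsample = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.downsample = Identity()

    def forward(self, x):
        y = self.relu(self.bn1(self.conv1(x)))
        y = self.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        return self.relu(y + self.downsample(x))


class ResNetBackbone(Module):
    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng(0)
        base = config.reduced_channels or 64
        self.stem = Sequential(
            Conv2d(3, base, 7, stride=config.stem_stride, padding=3, rng=rng),
            BatchNorm2d(base),
            ReLU(),
        )
        self.maxpool = MaxPool2d(3, stride=2, padding=1) if config.use_maxpool else Identity()
        widths = [base, base * 2, base * 4, base * 8]
        in_ch = base
        stages = []
        for i, (mid, nblocks) in enumerate(zip(widths, config.blocks)):
            stride = config.stage_strides[i]
            blocks = [Bottleneck(in_ch, mid, stride, config.groups, rng=rng)]
            in_ch = mid * Bottleneck.expansion
            for _ in range(nblocks - 1):
                blocks.append(Bottleneck(in_ch, mid, 1, config.groups, rng=rng))
            if config.cbam_enabled:
                blocks.append(CBAM(in_ch, config.cbam_reduction, rng=rng))
            stages.append(Sequential(*blocks))
        self.layer1, self.layer2, self.layer3, self.layer4 = stages
        self.out_channels = in_ch

    def forward(self, x):
        x = self.maxpool(self.stem(x))
        x = self.layer1(x)
        x = self.layer2(x)
        x = self.layer3(x)
        return self.layer4(x)


def build_backbone(config: BackboneConfig | None = None,
                   rng: np.random.Generator | None = None) -> ResNetBackbone:
    """Instantiate the feature-extraction backbone for a configuration."""
    return ResNetBackbone(config or BackboneConfig(), rng=rng)
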