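"""Adaptive spatial-channel feature fusion neck.

Three backbone levels (strides 8/16/32) are mapped to a common channel
width with 1x1 convolutions, bilinearly resized to a target level's
resolution, concatenated, passed through a sequential channel-then-spatial
attention block, and reduced back to the common width by a 1x1 convolution
followed by a 3x3 feature-extraction convolution. One fusion runs per
output scale; a stride-2 3x3 convolution of the fused coarsest map supplies
the fourth, stride-64 output, preserving the drop-in shape contract with the
plain channel-mapper neck it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, LayerNorm2d, Linear, Module, Tensor
from .nn import functional as F


@dataclass
class AttentionWeights:
    """Weights actually applied during one attention forward pass."""

    channel_weights: np.ndarray  # (batch, channels)
    spatial_map: np.ndarray      # (batch, 1, height, width)

    def __post_init__(self):
        if not ((self.channel_weights >= 0).all() and (self.channel_weights <= 1).all()):
            raise ValueError("channel weights must lie in [0, 1]")
        if not ((self.spatial_map >= 0).all() and (self.spatial_map <= 1).all()):
            raise ValueError("spatial map must lie in [0, 1]")


class SpatialChannelAttention(Module):
    """Sequential channel-then-spatial attention.

    Channel branch: global average pool -> two-layer bottleneck (reduction
    ``reduction``) -> logistic. Spatial branch: per-position mean and max
    over channels of the channel-reweighted map -> single ``spatial_kernel``
    convolution -> logistic.
    """

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng)
        # start with nearly-open gates (logistic ~0.88) so attention modulates
        # an intact signal instead of halving it at initialization
        self.fc2.bias.data[:] = 2.0
        self.spatial_conv.bias.data[:] = 2.0
        self.channels = channels

    def forward(self, x: Tensor, return_weights: bool = False):
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite values in attention input")
        n, c, h, w = x.shape
        pooled = F.global_avg_pool(x).reshape(n, c)
        cw = self.fc2(self.fc1(pooled).relu()).sigmoid()          # (n, c)
        x_c = x * cw.reshape(n, c, 1, 1)

        mean_map = x_c.mean(axis=1, keepdims=True)
        max_map = x_c.max(axis=1, keepdims=True)
        sw = self.spatial_conv(Tensor.concat([mean_map, max_map], axis=1)).sigmoid()
        out = x_c * sw
        if return_weights:
            return AttentionWeights(cw.data.copy(), sw.data.copy()), out
        return out


def spatial_channel_attention(x: Tensor | np.ndarray, block: SpatialChannelAttention):
    """Functional entry point returning ``(weights, output)``."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return block(x, return_weights=True)


class FuseBlock(Module):
    """Concatenate three aligned maps, attend, and extract features."""

    def __init__(self, out_channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        self.attention = SpatialChannelAttention(3 * out_channels, reduction,
                                                 spatial_kernel, rng=rng)
        self.reduce = Conv2d(3 * out_channels, out_channels, 1, rng=rng)
        self.reduce_norm = LayerNorm2d(out_channels)
        self.extract = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.extract_norm = LayerNorm2d(out_channels)
        self.out_channels = out_channels

    def forward(self, aligned: list[Tensor]) -> Tensor:
        shapes = {t.shape for t in aligned}
        if len(aligned) != 3 or len(shapes) != 1:
            raise ValueError("fusion requires three feature maps of identical shape")
        cat = Tensor.concat(aligned, axis=1)
        attended = self.attention(cat)
        return self.extract_norm(self.extract(
            self.reduce_norm(self.reduce(attended)).relu()))


class AscffNeck(Module):
    """Per-scale adaptive fusion neck producing four stride-8/16/32/64 maps."""

    def __init__(self, in_channels: tuple[int, int, int], out_channels: int = 256,
                 reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        if len(in_channels) != 3:
            raise ValueError("expected exactly three pyramid levels")
        self.laterals = [Conv2d(c, out_channels, 1, rng=rng) for c in in_channels]
        self.lateral_norms = [LayerNorm2d(out_channels) for _ in range(3)]
        self.fuse_blocks = [FuseBlock(out_channels, reduction, spatial_kernel, rng=rng)
                            for _ in range(3)]
        self.extra = Conv2d(out_channels, out_channels, 3, stride=2, padding=1, rng=rng)
        self.extra_norm = LayerNorm2d(out_channels)
        self.out_channels = out_channels

    def _check(self, pyramid: list[Tensor]) -> None:
        if len(pyramid) != 3:
            raise ValueError("expected a three-level pyramid")
        if len(self.laterals) != 3:
            raise ValueError("neck misconfigured")

    def align_levels(self, pyramid: list[Tensor], target_index: int) -> list[Tensor]:
        """Map all levels to the common width and the target level's size."""
        self._check(pyramid)
        if target_index not in (1, 2, 3):
            raise ValueError("target_index must be 1, 2 or 3")
        target = pyramid[target_index - 1]
        th, tw = target.shape[2], target.shape[3]
        return [F.bilinear_resize(norm(lat(level)), th, tw)
                for lat, norm, level in zip(self.laterals, self.lateral_norms, pyramid)]

    def fuse_at(self, pyramid: list[Tensor], target_index: int) -> Tensor:
        return self.fuse_blocks[target_index - 1](self.align_levels(pyramid, target_index))

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        self._check(pyramid)
        fused = [self.fuse_at(pyramid, i) for i in (1, 2, 3)]
        return fused + [self.extra_norm(self.extra(fused[2]))]


class ChannelMapperNeck(Module):
    """Baseline neck: per-level 1x1 convolutions plus a stride-2 extra map."""

    def __init__(self, in_channels: tuple[int, int, int], out_channels: int = 256,
                 rng: np.random.Generator | None = None):
        self.laterals = [Conv2d(c, out_channels, 1, rng=rng) for c in in_channels]
        self.lateral_norms = [LayerNorm2d(out_channels) for _ in range(3)]
        self.extra = Conv2d(out_channels, out_channels, 3, stride=2, padding=1, rng=rng)
        self.extra_norm = LayerNorm2d(out_channels)
        self.out_channels = out_channels

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        if len(pyramid) != 3:
            raise ValueError("expected a three-level pyramid")
        mapped = [norm(lat(level))
                  for lat, norm, level in zip(self.laterals, self.lateral_norms, pyramid)]
        return mapped + [self.extra_norm(self.extra(mapped[2]))]
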