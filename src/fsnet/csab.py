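"""Channel Spatial Attention Block (CSAB).

The block sits on a U-Net skip connection and receives two feature maps of
identical shape: the encoder (skip) feature ``x`` and the up-sampled decoder
(gate) feature ``g``.  It applies, in order:

1. *Channel attention* — separately for ``g`` and ``x``: global max- and
   average-pooled descriptors pass through a shared three-layer 1x1
   bottleneck (C -> C/8 -> C/8 -> C, ReLU after every layer), are
   concatenated (2C) and reduced by a 1x1 convolution to C, then squashed by
   a sigmoid into per-channel weights alpha1 (for g) and alpha2 (for x).
   The attended features are ``g_l = alpha1 * g`` and ``x_l = alpha2 * x``.
2. *Spatial attention* — ``g_l`` and ``x_l`` are projected by 1x1
   convolutions, concatenated, and reduced to a single channel; the sigmoid
   of that map is the spatial weight alpha3 (one value per pixel).  The
   block output of this stage is the triple product
   ``f = alpha3 * x_l * g_l`` (alpha3 broadcast over channels).
3. *Merge* — ``f`` is concatenated with the raw skip feature ``x`` (2C
   channels) and reduced to C channels by a final 1x1 convolution.

The bottleneck is shared between the max- and avg-pool branches of one
feature but not between the g- and x-side blocks.  The trailing ReLU of the
bottleneck is applied as specified; ``final_relu=False`` disables it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class AttentionWeights:
    """Attention coefficients of one CSAB forward pass (batched arrays)."""

    channel_g: np.ndarray  # alpha1, (N, C, 1, 1)
    channel_x: np.ndarray  # alpha2, (N, C, 1, 1)
    spatial: np.ndarray    # alpha3, (N, 1, H, W)


class ChannelAttention(nn.Module):
    """Squeeze-style channel gate: pooled descriptors -> shared bottleneck ->
    concat -> 1x1 reduce -> sigmoid, returning a (N, C, 1, 1) weight."""

    def __init__(self, channels: int, reduction: int = 8, final_relu: bool = True,
                 dtype=np.float32):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channel count {channels} must be divisible by {reduction}")
        hidden = channels // reduction
        self.fc1 = nn.Conv2d(channels, hidden, 1, dtype=dtype)
        self.fc2 = nn.Conv2d(hidden, hidden, 1, dtype=dtype)
        self.fc3 = nn.Conv2d(hidden, channels, 1, dtype=dtype)
        self.reduce = nn.Conv2d(2 * channels, channels, 1, dtype=dtype)
        self.final_relu = final_relu

    def _bottleneck(self, d: Tensor) -> Tensor:
        d = self.fc1(d).relu()
        d = self.fc2(d).relu()
        d = self.fc3(d)
        return d.relu() if self.final_relu else d

    def forward(self, feature: Tensor) -> Tensor:
        d_max = self._bottleneck(nn.global_max_pool(feature))
        d_avg = self._bottleneck(nn.global_avg_pool(feature))
        return self.reduce(nn.concat([d_max, d_avg], axis=1)).sigmoid()


class SpatialAttention(nn.Module):
    """Pixel-wise gate over the channel-attended pair (g_l, x_l)."""

    def __init__(self, channels: int, dtype=np.float32):
        super().__init__()
        self.w_g = nn.Conv2d(channels, channels, 1, dtype=dtype)
        self.w_x = nn.Conv2d(channels, channels, 1, dtype=dtype)
        self.psi = nn.Conv2d(2 * channels, 1, 1, dtype=dtype)

    def forward(self, g_l: Tensor, x_l: Tensor) -> tuple[Tensor, Tensor]:
        fused = nn.concat([self.w_g(g_l), self.w_x(x_l)], axis=1)
        alpha3 = self.psi(fused).sigmoid()
        f = alpha3 * x_l * g_l
        return alpha3, f


class CSAB(nn.Module):
    def __init__(self, channels: int, reduction: int = 8, final_relu: bool = True,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.cab_g = ChannelAttention(channels, reduction, final_relu, dtype)
        self.cab_x = ChannelAttention(channels, reduction, final_relu, dtype)
        self.sab = SpatialAttention(channels, dtype)
        self.merge = nn.Conv2d(2 * channels, channels, 1, dtype=dtype)

    def _check(self, x: Tensor, g: Tensor) -> None:
        if x.shape != g.shape:
            raise ValueError(f"x {x.shape} and g {g.shape} must match")
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        out, _ = self.forward_with_attention(x, g)
        return out

    def forward_with_attention(self, x: Tensor, g: Tensor) -> tuple[Tensor, AttentionWeights]:
        self._check(x, g)
        alpha1 = self.cab_g(g)
        alpha2 = self.cab_x(x)
        g_l = alpha1 * g
        x_l = alpha2 * x
        alpha3, f = self.sab(g_l, x_l)
        out = self.merge(nn.concat([f, x], axis=1))
        weights = AttentionWeights(alpha1.data.copy(), alpha2.data.copy(),
                                   alpha3.data.copy())
        return out, weights
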