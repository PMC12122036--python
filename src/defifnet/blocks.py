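"""The three bespoke layers of the network.

* :class:`FIFConv` — feature interaction fusion convolution.  A
  split–transform–gate–recombine operator: the input is torn into two channel
  halves, each half is lifted to full width by a 1x1 convolution, the left
  half goes through a 2-group 3x3 convolution plus a 1x1 shortcut, the right
  half through an identity residual plus a 1x1 convolution; the two are
  concatenated, gated per channel by a sigmoid of the global spatial average,
  torn again and summed, so the output width equals the input width.

* :class:`CFRM` — channel feature reconstruction module used on the skip
  connections.  One channel half is gated by a learnable affine of its global
  average pool, the other by a learnable affine of its group-normalized map
  after a grouped 3x3 convolution; the halves are concatenated and passed
  through a 2-group channel shuffle.  The affine scales initialize to zero and
  the shifts to one, so at initialization both gates equal sigmoid(1).

* :class:`MBGM` — multi-branch ghost module for the bottleneck: a 3x3 entry
  convolution, a ghost pair of 1x1 convolutions, an extra 3x3 branch fused
  residually, and a 3x3 exit convolution; every convolution is followed by
  batch normalization and ReLU.

FIFConv and CFRM keep their convolutions plain (conv + bias) by default; a
``norm_act`` flag optionally inserts BN + ReLU after each convolution.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm2d, Conv2d, ConvBNReLU, GroupNorm2d, Module


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Channel order produced by reshape(B, g, C/g, ...) -> swap -> flatten."""
    if channels % groups:
        raise ValueError(f"groups={groups} does not divide channels={channels}")
    return (np.arange(channels).reshape(groups, channels // groups).T).reshape(-1)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channels across `groups`; values are only permuted."""
    return ad.permute_channels(x, shuffle_permutation(x.shape[1], groups))


class FIFConv(Module):
    """Feature interaction fusion convolution, C channels in and out."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 norm_act: bool = False):
        super().__init__()
        if channels % 2:
            raise ValueError(f"FIFConv needs an even channel count, got {channels}")
        self.channels = channels
        half = channels // 2
        unit = ConvBNReLU if norm_act else Conv2d
        self.conv1_left = unit(half, channels, 1, rng)
        self.conv1_right = unit(half, channels, 1, rng)
        self.group_conv = unit(channels, channels, 3, rng, groups=2)
        self.inner_left = unit(channels, channels, 1, rng)
        self.inner_right = unit(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if x.shape[2] < 1 or x.shape[3] < 1:
            raise ValueError("spatial dimensions must be positive")
        x1, x2 = ad.chunk(x, 2)                       # tear
        x1 = self.conv1_left(x1)                      # lift C/2 -> C
        x2 = self.conv1_right(x2)
        x1 = self.group_conv(x1) + self.inner_left(x1)
        x2 = x2 + self.inner_right(x2)
        y = ad.concat([x1, x2])                       # 2C channels
        gate = ad.sigmoid(ad.global_avg_pool(y))      # per-channel scalar
        y = y * gate
        y1, y2 = ad.chunk(y, 2)                       # tear again
        return y1 + y2                                # recombine, C channels

    def gate_values(self, x: Tensor) -> np.ndarray:
        """The per-channel sigmoid gate for a given input (diagnostic)."""
        x1, x2 = ad.chunk(x, 2)
        x1 = self.conv1_left(x1)
        x2 = self.conv1_right(x2)
        x1 = self.group_conv(x1) + self.inner_left(x1)
        x2 = x2 + self.inner_right(x2)
        y = ad.concat([x1, x2])
        return ad.sigmoid(ad.global_avg_pool(y)).data


class CFRM(Module):
    """Channel feature reconstruction module, C channels in and out."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 gn_groups: int = 2, conv_groups: int = 2,
                 norm_act: bool = False):
        super().__init__()
        if channels % 2:
            raise ValueError(f"CFRM needs an even channel count, got {channels}")
        half = channels // 2
        if half % gn_groups:
            raise ValueError(
                f"gn_groups={gn_groups} must divide half the channels ({half})")
        if half % conv_groups:
            raise ValueError(
                f"conv_groups={conv_groups} must divide half the channels ({half})")
        self.channels = channels
        # learnable scale/shift: zeros / ones, as pinned by the module design
        self.w_gap = self.register_param("w_gap", np.zeros((1, half, 1, 1)))
        self.b_gap = self.register_param("b_gap", np.ones((1, half, 1, 1)))
        self.w_gn = self.register_param("w_gn", np.zeros((1, half, 1, 1)))
        self.b_gn = self.register_param("b_gn", np.ones((1, half, 1, 1)))
        if norm_act:
            self.branch2_conv = ConvBNReLU(half, half, 3, rng, groups=conv_groups)
        else:
            self.branch2_conv = Conv2d(half, half, 3, rng, groups=conv_groups)
        self.gn = GroupNorm2d(gn_groups, half, affine=False)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        x1, x2 = ad.chunk(x, 2)
        y1 = x1 * ad.sigmoid(ad.global_avg_pool(x1) * self.w_gap + self.b_gap)
        y2 = self.branch2_conv(x2) * ad.sigmoid(self.gn(x2) * self.w_gn + self.b_gn)
        y = ad.concat([y1, y2])
        return channel_shuffle(y, 2)


class MBGM(Module):
    """Multi-branch ghost module: C_in -> C_out through a width-C_b core."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.mid_ch, self.out_ch = in_ch, mid_ch, out_ch
        self.entry = ConvBNReLU(in_ch, mid_ch, 3, rng)
        self.primary = ConvBNReLU(mid_ch, mid_ch, 1, rng)
        self.secondary = ConvBNReLU(mid_ch, mid_ch, 1, rng)
        self.branch = ConvBNReLU(mid_ch, mid_ch, 3, rng)
        self.exit = ConvBNReLU(2 * mid_ch, out_ch, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        y = self.entry(x)                 # higher-level features
        p = self.primary(y)               # ghost primary path
        q = self.secondary(p)             # cheap ghost half
        r = self.branch(p)                # extra 3x3 feature branch
        return self.exit(ad.concat([q, p + r]))
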