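"""CoTResNet3D: a 3-stage 3D residual backbone with contextual dynamic
convolution (CoT) and squeeze-and-excitation (SE3D) blocks.

The stem halves resolution twice (7x7x7 stride-2 convolution, then 3x3x3
stride-2 max pooling); stages 2 and 3 halve it again, for a total stride of
16.  On the standard 84x102x84 input the stage outputs are 64x21x26x21,
128x11x13x11 and 256x6x7x6.

The CoT block predicts, from a grouped-convolution context embedding, a
per-location softmax weighting over the 27 positions of each voxel's 3x3x3
neighborhood, aggregates the (factor-2 average-pooled) value field with
those dynamic weights, projects back to the input width, and adds the
correction through a learnable scalar gate initialized at 0.5.  One weight
set is shared by all channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, Module, Sequential, Identity, Conv3d, BatchNorm3d,
                 Dropout3d, concat)
from .nn import functional as F


@dataclass
class BackboneConfig:
    in_channels: int = 1
    stem_channels: int = 64
    stage_channels: tuple = (64, 128, 256)
    blocks_per_stage: tuple = (2, 2, 2)
    cot_enabled_stages: tuple = (2, 3)    # 1-based stage indices
    cot_kernel: int = 3                   # -> K = 27 dynamic weights per location
    cot_groups: int = 4
    cot_hidden_divisor: int = 8           # hidden width = C / 8
    cot_pool_factor: int = 2
    cot_gate_init: float = 0.5
    se_enabled: bool = True
    se_reduction: int = 4                 # hidden = C/4, rounded to a multiple of 8
    block_dropout: float = 0.1

    def __post_init__(self):
        for s in self.cot_enabled_stages:
            ch = self.stage_channels[s - 1]
            if ch % self.cot_groups:
                raise ValueError(
                    f"stage {s} channels {ch} not divisible by cot_groups={self.cot_groups}")


def se_hidden_width(channels: int, reduction: int = 4) -> int:
    """C/reduction, floored at 8 and rounded to the nearest multiple of 8."""
    h = max(8, channels // reduction)
    return max(8, int(round(h / 8)) * 8)


def cot_hidden_width(channels: int, divisor: int = 8) -> int:
    return max(1, channels // divisor)


class SE3d(Module):
    """Squeeze-and-excitation channel gate for volumetric features."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        self.hidden = se_hidden_width(channels, reduction)
        self.fc1 = Conv3d(channels, self.hidden, 1)
        self.fc2 = Conv3d(self.hidden, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3, 4), keepdims=True)
        gate = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * gate


class CoT3d(Module):
    """Contextual dynamic-kernel module over the 3x3x3 neighborhood (K = 27)."""

    K = 27

    def __init__(self, channels: int, groups: int = 4, hidden_divisor: int = 8,
                 pool_factor: int = 2, gate_init: float = 0.5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels = channels
        self.pool_factor = pool_factor
        self.hidden = cot_hidden_width(channels, hidden_divisor)
        self.context = Conv3d(channels, channels, 3, padding=1, groups=groups)
        self.reduce = Conv3d(2 * channels, self.hidden, 1)
        self.to_weights = Conv3d(self.hidden, self.K, 1)
        self.proj = Conv3d(channels, channels, 1)
        self.gate = Tensor(np.array([gate_init], np.float32), requires_grad=True)

    def context_weights(self, x: Tensor, value_grid=None) -> Tensor:
        """Per-location dynamic weights on the pooled grid, softmax over K=27."""
        ctx = self.context(x)
        h = self.reduce(concat([x, ctx], axis=1)).relu()
        w = self.to_weights(h)
        w = F.avg_pool3d_ceil(w, self.pool_factor)
        if value_grid is not None and w.data.shape[2:] != tuple(value_grid):
            w = F.resize_trilinear(w, value_grid)
        return w.softmax(axis=1)

    def aggregate(self, x: Tensor, weights: Tensor) -> Tensor:
        """Weighted 3x3x3 aggregation of the pooled value field, resized back."""
        v = F.avg_pool3d_ceil(x, self.pool_factor)
        if weights.data.shape[2:] != v.data.shape[2:]:
            raise ValueError(
                f"weight grid {weights.data.shape[2:]} does not match pooled value "
                f"grid {v.data.shape[2:]}")
        unf = F.unfold27(v)                              # (B, C, 27, d, h, w)
        wexp = weights.reshape(weights.data.shape[0], 1, self.K, *weights.data.shape[2:])
        agg = (unf * wexp).sum(axis=2)                   # shared across channels
        agg = F.resize_trilinear(agg, x.data.shape[2:])
        return self.proj(agg)

    def forward(self, x: Tensor) -> Tensor:
        pooled = tuple(-(-n // self.pool_factor) for n in x.data.shape[2:])
        w = self.context_weights(x, value_grid=pooled)
        corr = self.aggregate(x, w)
        return x + self.gate.reshape(1, 1, 1, 1, 1) * corr


class ResidualBlock3d(Module):
    """conv-BN-ReLU-conv-BN [-CoT] [-SE3D] -dropout + shortcut -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 cfg: BackboneConfig | None = None, use_cot: bool = False):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = BatchNorm3d(out_ch)
        self.cot = CoT3d(out_ch, cfg.cot_groups, cfg.cot_hidden_divisor,
                         cfg.cot_pool_factor, cfg.cot_gate_init) if use_cot else None
        self.se = SE3d(out_ch, cfg.se_reduction) if cfg.se_enabled else None
        self.drop = Dropout3d(cfg.block_dropout)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(Conv3d(in_ch, out_ch, 1, stride=stride,
                                              bias=False), BatchNorm3d(out_ch))
        else:
            self.shortcut = Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.cot is not None:
            out = self.cot(out)
        if self.se is not None:
            out = self.se(out)
        out = self.drop(out)
        return (out + self.shortcut(x)).relu()


@dataclass
class FeatureMaps:
    stage1: Tensor
    stage2: Tensor
    stage3: Tensor


class CoTResNet3D(Module):
    """Single-channel volume -> three multi-scale feature maps."""

    MIN_SPATIAL = 8

    def __init__(self, cfg: BackboneConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or BackboneConfig()
        c0 = cfg.stem_channels
        self.stem_conv = Conv3d(cfg.in_channels, c0, 7, stride=2, padding=3, bias=False)
        self.stem_bn = BatchNorm3d(c0)
        in_ch = c0
        for s, (ch, nblocks) in enumerate(zip(cfg.stage_channels, cfg.blocks_per_stage),
                                          start=1):
            blocks = []
            for b in range(nblocks):
                stride = 2 if (s > 1 and b == 0) else 1
                blocks.append(ResidualBlock3d(in_ch, ch, stride, cfg,
                                              use_cot=s in cfg.cot_enabled_stages))
                in_ch = ch
            setattr(self, f"stage{s}", Sequential(*blocks))

    def forward(self, x: Tensor) -> FeatureMaps:
        if x.data.ndim != 5 or x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels}-channel input "
                f"(B, {self.cfg.in_channels}, D, H, W), got {x.data.shape}")
        if min(x.data.shape[2:]) < self.MIN_SPATIAL:
            raise ValueError(
                f"spatial dims {x.data.shape[2:]} too small for four stride-2 "
                f"reductions; minimum is {self.MIN_SPATIAL} per axis")
        h = F.max_pool3d(self.stem_bn(self.stem_conv(x)).relu(), 3, 2, 1)
        s1 = self.stage1(h)
        s2 = self.stage2(s1)
        s3 = self.stage3(s2)
        return FeatureMaps(s1, s2, s3)


def backbone_stage_shapes(input_shape) -> dict:
    """Shape trace from conv/pool arithmetic, without running any weights."""

    def down(n, k, s, p):
        return (n + 2 * p - k) // s + 1

    sp = tuple(input_shape)
    trace = {"input": sp}
    sp = tuple(down(n, 7, 2, 3) for n in sp)
    trace["stem_conv"] = sp
    sp = tuple(down(n, 3, 2, 1) for n in sp)
    trace["stage1"] = sp
    sp2 = tuple(down(n, 3, 2, 1) for n in sp)
    trace["stage2"] = sp2
    sp3 = tuple(down(n, 3, 2, 1) for n in sp2)
    trace["stage3"] = sp3
    return trace
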