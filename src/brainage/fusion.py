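"""Cross-scale CrossViT fusion head, the assembled ResNet-CrossViT model and
its three ablation baselines.

Two token streams are formed from the backbone: the *large* stream from the
stage-2 feature map (128 channels, embedded at 160) and the *small* stream
from stage 3 (256 channels, embedded at 96), each through a non-overlapping
2x2x2 cube projection.  Patch tokens receive a 3-D sinusoidal positional
encoding split across the z/y/x axes; a learnable cls token (truncated
normal, sd 0.02, no positional encoding) heads each sequence.  Each fusion
layer runs small-stream self-attention, large-stream self-attention, then
gated bidirectional cross-attention in which each stream's cls queries the
other stream's patches.  Residual branches carry LayerScale (gamma init
1e-4) and stochastic depth.  The regression head concatenates the two
normalized cls tokens (96 + 160 = 256) and maps 256 -> 192 -> 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, CoTResNet3D, backbone_stage_shapes
from .nn import (Tensor, Module, Sequential, Identity, Conv3d, Linear,
                 LayerNorm, Dropout, DropPath, concat, trunc_normal)
from .nn import functional as F


@dataclass
class FusionConfig:
    small_embed_dim: int = 96         # tokens from stage 3 (256 ch)
    large_embed_dim: int = 160        # tokens from stage 2 (128 ch)
    patch_size: int = 2               # cube kernel = stride, no padding
    heads: int = 4
    mlp_ratio: int = 4
    attn_drop: float = 0.1
    dropout: float = 0.1
    drop_path_total: float = 0.1      # schedule 0.0, 0.1 over depth 2
    layerscale_init: float = 1e-4
    cls_init_std: float = 0.02
    cross_gate_init: float = 0.1      # gate_s and gate_l
    depth: int = 2
    token_keep_rate: float = 1.0
    freeze_backbone: bool = False
    head_hidden: int = 192

    def __post_init__(self):
        for d in (self.small_embed_dim, self.large_embed_dim):
            if d % self.heads:
                raise ValueError(f"embed dim {d} not divisible by {self.heads} heads")
        if not (0.0 < self.token_keep_rate <= 1.0):
            raise ValueError(f"token_keep_rate must be in (0, 1], got {self.token_keep_rate}")

    def drop_path_schedule(self):
        if self.depth == 1:
            return [self.drop_path_total]
        return [self.drop_path_total * i / (self.depth - 1) for i in range(self.depth)]


# ---------------------------------------------------------------------------
# tokenization and positional encoding
# ---------------------------------------------------------------------------

def axis_split(dim: int) -> tuple[int, int, int]:
    """Split an embedding width across the z, y, x axes.

    The base is dim // 3 adjusted up to an even number and assigned to z and
    y; x absorbs the (even) remainder, e.g. 96 -> (32, 32, 32) and
    160 -> (54, 54, 52).
    """
    if dim < 6:
        raise ValueError(f"embedding dim {dim} too small for a 3-axis split (minimum 6)")
    if dim % 2:
        raise ValueError(f"embedding dim must be even, got {dim}")
    base = dim // 3
    base += base % 2
    dx = dim - 2 * base
    if dx < 2:
        raise ValueError(f"embedding dim {dim} leaves no room for the x axis")
    return base, base, dx


def _axis_encoding(length: int, width: int) -> np.ndarray:
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(width // 2, dtype=np.float64)[None, :]
    freq = np.power(10000.0, 2.0 * i / width)
    enc = np.empty((length, width), dtype=np.float64)
    enc[:, 0::2] = np.sin(pos / freq)
    enc[:, 1::2] = np.cos(pos / freq)
    return enc


def sinusoidal_pe_3d(grid, dim: int) -> np.ndarray:
    """(N, dim) table of concatenated per-axis sine/cosine encodings."""
    D, H, W = grid
    dz, dy, dx = axis_split(dim)
    ez = _axis_encoding(D, dz)
    ey = _axis_encoding(H, dy)
    ex = _axis_encoding(W, dx)
    pe = np.empty((D, H, W, dim), dtype=np.float32)
    pe[..., :dz] = ez[:, None, None, :]
    pe[..., dz:dz + dy] = ey[None, :, None, :]
    pe[..., dz + dy:] = ex[None, None, :, :]
    return pe.reshape(D * H * W, dim)


class PatchEmbed3d(Module):
    """Non-overlapping cube projection: (B,C,D,H,W) -> (B,N,dim)."""

    def __init__(self, in_ch: int, dim: int, patch: int = 2):
        super().__init__()
        self.patch = patch
        self.proj = Conv3d(in_ch, dim, patch, stride=patch, padding=0)

    def token_grid(self, spatial):
        return tuple(n // self.patch for n in spatial)

    def forward(self, x: Tensor) -> Tensor:
        if min(x.data.shape[2:]) < self.patch:
            raise ValueError(
                f"spatial dims {x.data.shape[2:]} smaller than patch {self.patch}")
        h = self.proj(x)
        B, C = h.data.shape[:2]
        n = int(np.prod(h.data.shape[2:]))
        return h.reshape(B, C, n).transpose(0, 2, 1)


def token_prune(tokens: Tensor, keep_rate: float, rng, training: bool) -> Tensor:
    """Randomly retain ceil(keep_rate * N) patch tokens; cls (index 0) always kept.

    A no-op in evaluation mode and at keep_rate = 1.
    """
    if not training or keep_rate >= 1.0:
        return tokens
    n_patches = tokens.data.shape[1] - 1
    n_keep = math.ceil(keep_rate * n_patches)
    idx = np.sort(rng.choice(n_patches, size=n_keep, replace=False)) + 1
    idx = np.concatenate([[0], idx])
    return tokens[:, idx]


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------

class LayerScale(Module):
    def __init__(self, dim: int, init: float = 1e-4):
        super().__init__()
        self.gamma = Tensor(np.full(dim, init, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gamma


class Mlp(Module):
    def __init__(self, dim: int, ratio: int = 4, drop: float = 0.1):
        super().__init__()
        self.fc1 = Linear(dim, dim * ratio, init_std=0.02)
        self.fc2 = Linear(dim * ratio, dim, init_std=0.02)
        self.drop = Dropout(drop)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.drop(self.fc1(x).gelu())))


class MultiHeadAttention(Module):
    """Self-attention over (B, N, dim) with output-projection dropout."""

    def __init__(self, dim: int, heads: int, attn_drop: float = 0.1):
        super().__init__()
        self.heads, self.dim = heads, dim
        self.dh = dim // heads
        self.qkv = Linear(dim, 3 * dim, init_std=0.02)
        self.out = Linear(dim, dim, init_std=0.02)
        self.drop = Dropout(attn_drop)

    def forward(self, x: Tensor) -> Tensor:
        B, N, _ = x.data.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.heads, self.dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]      # (B, h, N, dh)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, self.dim)
        return self.drop(self.out(out))


class CrossHeadAttention(Module):
    """Multi-head attention of a single query token over a key/value sequence."""

    def __init__(self, dim: int, heads: int, attn_drop: float = 0.1):
        super().__init__()
        self.heads, self.dim = heads, dim
        self.dh = dim // heads
        self.q = Linear(dim, dim, init_std=0.02)
        self.kv = Linear(dim, 2 * dim, init_std=0.02)
        self.out = Linear(dim, dim, init_std=0.02)
        self.drop = Dropout(attn_drop)

    def forward(self, query: Tensor, kv: Tensor) -> Tensor:
        B, N, _ = kv.data.shape
        q = self.q(query).reshape(B, 1, self.heads, self.dh).transpose(0, 2, 1, 3)
        kvp = self.kv(kv).reshape(B, N, 2, self.heads, self.dh).transpose(2, 0, 3, 1, 4)
        k, v = kvp[0], kvp[1]
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, 1, self.dim)
        return self.drop(self.out(out))


class SelfAttentionBlock(Module):
    """Pre-norm transformer block with LayerScale and stochastic depth."""

    def __init__(self, dim: int, heads: int = 4, mlp_ratio: int = 4,
                 attn_drop: float = 0.1, drop: float = 0.1,
                 drop_path: float = 0.0, layerscale_init: float = 1e-4):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, attn_drop)
        self.ls1 = LayerScale(dim, layerscale_init)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, drop)
        self.ls2 = LayerScale(dim, layerscale_init)
        self.dp = DropPath(drop_path)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.dp(self.ls1(self.attn(self.ln1(x))))
        return x + self.dp(self.ls2(self.mlp(self.ln2(x))))


class _CrossDirection(Module):
    """One direction of cross-scale fusion: own cls attends to other patches.

    The scalar gate multiplies both residual updates (attention and MLP), so
    a zero gate leaves the cls token untouched.
    """

    def __init__(self, own_dim: int, other_dim: int, heads: int,
                 mlp_ratio: int, attn_drop: float, drop: float,
                 drop_path: float, layerscale_init: float, gate_init: float):
        super().__init__()
        self.ln_q = LayerNorm(own_dim)
        self.proj_fwd = Linear(own_dim, other_dim, init_std=0.02)
        self.ln_kv = LayerNorm(other_dim)
        self.attn = CrossHeadAttention(other_dim, heads, attn_drop)
        self.proj_back = Linear(other_dim, own_dim, init_std=0.02)
        self.ls1 = LayerScale(own_dim, layerscale_init)
        self.ln2 = LayerNorm(own_dim)
        self.mlp = Mlp(own_dim, mlp_ratio, drop)
        self.ls2 = LayerScale(own_dim, layerscale_init)
        self.dp = DropPath(drop_path)
        self.gate = Tensor(np.array([gate_init], np.float32), requires_grad=True)

    def forward(self, own_cls: Tensor, other_patches: Tensor) -> Tensor:
        q = self.proj_fwd(self.ln_q(own_cls))
        upd = self.proj_back(self.attn(q, self.ln_kv(other_patches)))
        own_cls = own_cls + self.gate * self.dp(self.ls1(upd))
        return own_cls + self.gate * self.dp(self.ls2(self.mlp(self.ln2(own_cls))))


class CrossAttentionBlock(Module):
    """Gated bidirectional cls <-> patches exchange between the two streams."""

    def __init__(self, small_dim: int, large_dim: int, heads: int = 4,
                 mlp_ratio: int = 4, attn_drop: float = 0.1, drop: float = 0.1,
                 drop_path: float = 0.0, layerscale_init: float = 1e-4,
                 gate_init: float = 0.1):
        super().__init__()
        self.small_to_large = _CrossDirection(small_dim, large_dim, heads, mlp_ratio,
                                              attn_drop, drop, drop_path,
                                              layerscale_init, gate_init)
        self.large_to_small = _CrossDirection(large_dim, small_dim, heads, mlp_ratio,
                                              attn_drop, drop, drop_path,
                                              layerscale_init, gate_init)

    @property
    def gate_s(self):
        return self.small_to_large.gate

    @property
    def gate_l(self):
        return self.large_to_small.gate

    def forward(self, small: Tensor, large: Tensor):
        if small.data.shape[1] < 2 or large.data.shape[1] < 2:
            raise ValueError("cross-attention needs a cls token plus patch tokens")
        cls_s, patch_s = small[:, 0:1], small[:, 1:]
        cls_l, patch_l = large[:, 0:1], large[:, 1:]
        new_s = self.small_to_large(cls_s, patch_l)
        new_l = self.large_to_small(cls_l, patch_s)
        return concat([new_s, patch_s], axis=1), concat([new_l, patch_l], axis=1)


class RegressionHead(Module):
    """Per-stream LN -> concat (256) -> LN -> 192 -> GELU -> dropout -> 1."""

    def __init__(self, small_dim: int = 96, large_dim: int = 160,
                 hidden: int = 192, drop: float = 0.1):
        super().__init__()
        self.ln_s = LayerNorm(small_dim)
        self.ln_l = LayerNorm(large_dim)
        self.ln = LayerNorm(small_dim + large_dim)
        self.fc1 = Linear(small_dim + large_dim, hidden, init_std=0.02)
        self.drop = Dropout(drop)
        self.fc2 = Linear(hidden, 1, init_std=0.02)

    def forward(self, cls_small: Tensor, cls_large: Tensor) -> Tensor:
        h = concat([self.ln_s(cls_small), self.ln_l(cls_large)], axis=-1)
        return self.fc2(self.drop(self.fc1(self.ln(h)).gelu()))


# ---------------------------------------------------------------------------
# assembled models
# ---------------------------------------------------------------------------

class _FusionLayer(Module):
    def __init__(self, cfg: FusionConfig, drop_path: float):
        super().__init__()
        kw = dict(heads=cfg.heads, mlp_ratio=cfg.mlp_ratio, attn_drop=cfg.attn_drop,
                  drop=cfg.dropout, drop_path=drop_path,
                  layerscale_init=cfg.layerscale_init)
        self.sa_small = SelfAttentionBlock(cfg.small_embed_dim, **kw)
        self.sa_large = SelfAttentionBlock(cfg.large_embed_dim, **kw)
        self.cross = CrossAttentionBlock(cfg.small_embed_dim, cfg.large_embed_dim,
                                         gate_init=cfg.cross_gate_init, **kw)

    def forward(self, small: Tensor, large: Tensor):
        small = self.sa_small(small)
        large = self.sa_large(large)
        return self.cross(small, large)


class ResNetCrossViT(Module):
    """Full model: volume -> CoTResNet3D -> dual-stream CrossViT -> age."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 fusion_cfg: FusionConfig | None = None):
        super().__init__()
        self.backbone_cfg = backbone_cfg = backbone_cfg or BackboneConfig()
        self.fusion_cfg = cfg = fusion_cfg or FusionConfig()
        self.backbone = CoTResNet3D(backbone_cfg)
        ch2, ch3 = backbone_cfg.stage_channels[1], backbone_cfg.stage_channels[2]
        self.embed_small = PatchEmbed3d(ch3, cfg.small_embed_dim, cfg.patch_size)
        self.embed_large = PatchEmbed3d(ch2, cfg.large_embed_dim, cfg.patch_size)
        self.cls_small = Tensor(trunc_normal((1, 1, cfg.small_embed_dim),
                                             std=cfg.cls_init_std), requires_grad=True)
        self.cls_large = Tensor(trunc_normal((1, 1, cfg.large_embed_dim),
                                             std=cfg.cls_init_std), requires_grad=True)
        for i, dp in enumerate(cfg.drop_path_schedule()):
            setattr(self, f"layer{i}", _FusionLayer(cfg, dp))
        self.head = RegressionHead(cfg.small_embed_dim, cfg.large_embed_dim,
                                   cfg.head_hidden, cfg.dropout)
        self._pe_cache: dict = {}

    def _tokens(self, featmap: Tensor, embed: PatchEmbed3d, cls: Tensor) -> Tensor:
        tokens = embed(featmap)
        grid = embed.token_grid(featmap.data.shape[2:])
        dim = tokens.data.shape[2]
        key = (grid, dim)
        if key not in self._pe_cache:
            self._pe_cache[key] = sinusoidal_pe_3d(grid, dim)[None]
        tokens = tokens + Tensor(self._pe_cache[key])
        B = tokens.data.shape[0]
        cls_b = cls + Tensor(np.zeros((B, 1, dim), np.float32))  # broadcast over batch
        tokens = concat([cls_b, tokens], axis=1)
        return token_prune(tokens, self.fusion_cfg.token_keep_rate, self._rng,
                           self.training)

    def forward(self, x: Tensor) -> Tensor:
        fm = self.backbone(x)
        small = self._tokens(fm.stage3, self.embed_small, self.cls_small)
        large = self._tokens(fm.stage2, self.embed_large, self.cls_large)
        for i in range(self.fusion_cfg.depth):
            small, large = getattr(self, f"layer{i}")(small, large)
        out = self.head(small[:, 0:1], large[:, 0:1])
        return out.reshape(out.data.shape[0])


class ResNetOnly(Module):
    """Ablation: the CNN branch alone with global average pooling."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None):
        super().__init__()
        self.backbone_cfg = backbone_cfg = backbone_cfg or BackboneConfig()
        self.backbone = CoTResNet3D(backbone_cfg)
        self.fc = Linear(backbone_cfg.stage_channels[-1], 1, init_std=0.02)

    def forward(self, x: Tensor) -> Tensor:
        fm = self.backbone(x)
        out = self.fc(F.global_avg_pool(fm.stage3))
        return out.reshape(out.data.shape[0])


@dataclass
class ViTConfig:
    patch_size: int = 16
    embed_dim: int = 384
    depth: int = 12
    heads: int = 6
    mlp_ratio: int = 4
    attn_drop: float = 0.1
    dropout: float = 0.1
    drop_path_total: float = 0.1
    layerscale_init: float = 1e-4


class ViTOnly(Module):
    """Ablation: 16x16x16 patches of the raw volume into a deep encoder."""

    def __init__(self, cfg: ViTConfig | None = None, in_channels: int = 1):
        super().__init__()
        self.cfg = cfg = cfg or ViTConfig()
        self.embed = PatchEmbed3d(in_channels, cfg.embed_dim, cfg.patch_size)
        self.cls = Tensor(trunc_normal((1, 1, cfg.embed_dim), std=0.02),
                          requires_grad=True)
        sched = (np.linspace(0, cfg.drop_path_total, cfg.depth)
                 if cfg.depth > 1 else [cfg.drop_path_total])
        for i in range(cfg.depth):
            setattr(self, f"block{i}", SelfAttentionBlock(
                cfg.embed_dim, cfg.heads, cfg.mlp_ratio, cfg.attn_drop,
                cfg.dropout, float(sched[i]), cfg.layerscale_init))
        self.ln = LayerNorm(cfg.embed_dim)
        self.fc = Linear(cfg.embed_dim, 1, init_std=0.02)
        self._pe_cache: dict = {}

    def encode(self, x: Tensor) -> Tensor:
        tokens = self.embed(x)
        grid = self.embed.token_grid(x.data.shape[2:])
        key = (grid, tokens.data.shape[2])
        if key not in self._pe_cache:
            self._pe_cache[key] = sinusoidal_pe_3d(grid, tokens.data.shape[2])[None]
        tokens = tokens + Tensor(self._pe_cache[key])
        B = tokens.data.shape[0]
        cls_b = self.cls + Tensor(np.zeros((B, 1, tokens.data.shape[2]), np.float32))
        tokens = concat([cls_b, tokens], axis=1)
        for i in range(self.cfg.depth):
            tokens = getattr(self, f"block{i}")(tokens)
        return self.ln(tokens[:, 0])

    def forward(self, x: Tensor) -> Tensor:
        out = self.fc(self.encode(x))
        return out.reshape(out.data.shape[0])


class ResNetViTConcat(Module):
    """Ablation: pooled CNN features concatenated with the ViT cls, no
    cross-attention; two-layer head mirroring the main regression head."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 vit_cfg: ViTConfig | None = None, head_hidden: int = 192,
                 drop: float = 0.1):
        super().__init__()
        self.backbone_cfg = backbone_cfg = backbone_cfg or BackboneConfig()
        self.backbone = CoTResNet3D(backbone_cfg)
        self.vit = ViTOnly(vit_cfg, backbone_cfg.in_channels)
        width = backbone_cfg.stage_channels[-1] + self.vit.cfg.embed_dim
        self.ln = LayerNorm(width)
        self.fc1 = Linear(width, head_hidden, init_std=0.02)
        self.drop = Dropout(drop)
        self.fc2 = Linear(head_hidden, 1, init_std=0.02)

    def forward(self, x: Tensor) -> Tensor:
        pooled = F.global_avg_pool(self.backbone(x).stage3)
        h = concat([pooled, self.vit.encode(x)], axis=-1)
        out = self.fc2(self.drop(self.fc1(self.ln(h)).gelu()))
        return out.reshape(out.data.shape[0])


BASELINE_KINDS = ("resnet_only", "vit_only", "resnet_vit_concat")
MODEL_KINDS = ("crossvit",) + BASELINE_KINDS


def build_model(backbone_cfg: BackboneConfig | None = None,
                fusion_cfg: FusionConfig | None = None,
                seed: int = 0) -> ResNetCrossViT:
    """Deterministically construct the full model from its configs."""
    from .nn import manual_seed
    manual_seed(seed)
    model = ResNetCrossViT(backbone_cfg, fusion_cfg)
    model.seed_stochastic(seed + 1)
    return model


def build_baseline(kind: str, backbone_cfg: BackboneConfig | None = None,
                   vit_cfg: ViTConfig | None = None, seed: int = 0) -> Module:
    from .nn import manual_seed
    manual_seed(seed)
    if kind == "resnet_only":
        model = ResNetOnly(backbone_cfg)
    elif kind == "vit_only":
        model = ViTOnly(vit_cfg)
    elif kind == "resnet_vit_concat":
        model = ResNetViTConcat(backbone_cfg, vit_cfg)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")
    model.seed_stochastic(seed + 1)
    return model


def inspect_shapes(input_shape, backbone_cfg: BackboneConfig | None = None,
                   fusion_cfg: FusionConfig | None = None) -> dict:
    """Stage shapes, token counts and PE axis splits from pure arithmetic."""
    backbone_cfg = backbone_cfg or BackboneConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    if min(input_shape) < CoTResNet3D.MIN_SPATIAL:
        raise ValueError(
            f"input {tuple(input_shape)} too small; minimum spatial size is "
            f"{CoTResNet3D.MIN_SPATIAL} per axis")
    trace = backbone_stage_shapes(input_shape)
    p = fusion_cfg.patch_size
    small_grid = tuple(n // p for n in trace["stage3"])
    large_grid = tuple(n // p for n in trace["stage2"])
    if min(small_grid) < 1 or min(large_grid) < 1:
        raise ValueError(
            f"input {tuple(input_shape)} too small for {p}^3 patching of the "
            f"stage feature maps (stage3 {trace['stage3']}, stage2 {trace['stage2']})")
    return {
        "input": tuple(input_shape),
        "stem_conv": trace["stem_conv"],
        "stage_shapes": {
            "stage1": (backbone_cfg.stage_channels[0],) + trace["stage1"],
            "stage2": (backbone_cfg.stage_channels[1],) + trace["stage2"],
            "stage3": (backbone_cfg.stage_channels[2],) + trace["stage3"],
        },
        "small_stream": {"grid": small_grid, "patches": int(np.prod(small_grid)),
                         "embed_dim": fusion_cfg.small_embed_dim,
                         "axis_split": axis_split(fusion_cfg.small_embed_dim)},
        "large_stream": {"grid": large_grid, "patches": int(np.prod(large_grid)),
                         "embed_dim": fusion_cfg.large_embed_dim,
                         "axis_split": axis_split(fusion_cfg.large_embed_dim)},
        "vit_only_patches": int(np.prod([n // 16 for n in input_shape])),
    }
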