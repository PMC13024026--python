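"""Volumetric neural-network primitives (conv, pooling, resampling, unfold).

All spatial operators act on arrays laid out as (batch, channels, D, H, W).
3D convolution is evaluated as an im2col + batched matmul; its backward pass
scatters column gradients back with a loop over the (small) set of kernel
offsets.  Trilinear resampling is expressed as three separable 1-D linear
interpolation matrices under the half-pixel-center convention, which makes
its adjoint (the backward pass) a transpose matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor


def _triple(v):
    if isinstance(v, (tuple, list)):
        return tuple(v)
    return (v, v, v)


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k, s, out_sp):
    """View a padded (B,C,D,H,W) array as (B,C,kd,kh,kw,Do,Ho,Wo) columns."""
    B, C, D, H, W = xp.shape
    kd, kh, kw = k
    sd, sh, sw = s
    Do, Ho, Wo = out_sp
    sb, sc, s0, s1, s2 = xp.strides
    view = as_strided(
        xp,
        shape=(B, C, kd, kh, kw, Do, Ho, Wo),
        strides=(sb, sc, s0, s1, s2, s0 * sd, s1 * sh, s2 * sw),
        writeable=False,
    )
    return view


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=1, padding=0,
           groups: int = 1) -> Tensor:
    """Grouped 3-D cross-correlation.

    x: (B, Cin, D, H, W); weight: (Cout, Cin//groups, kd, kh, kw); bias: (Cout,).
    """
    k = weight.data.shape[2:]
    s = _triple(stride)
    p = _triple(padding)
    B, Cin, D, H, W = x.data.shape
    Cout = weight.data.shape[0]
    if Cin % groups or Cout % groups:
        raise ValueError(f"channels ({Cin}->{Cout}) not divisible by groups={groups}")
    if weight.data.shape[1] != Cin // groups:
        raise ValueError("weight shape inconsistent with input channels/groups")
    out_sp = tuple(conv_out_size(n, kk, ss, pp) for n, kk, ss, pp in zip((D, H, W), k, s, p))
    if min(out_sp) < 1:
        raise ValueError(f"input {D,H,W} too small for kernel {k} stride {s} padding {p}")

    pw = ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2]))
    xp = np.pad(x.data, pw)
    cols = np.ascontiguousarray(_im2col(xp, k, s, out_sp))
    L = int(np.prod(out_sp))
    ck = (Cin // groups) * k[0] * k[1] * k[2]
    # (B, g, ck, L)
    cols_m = cols.reshape(B, groups, ck, L)
    w_m = weight.data.reshape(groups, Cout // groups, ck)
    out = np.matmul(w_m[None], cols_m)  # (B, g, Cout/g, L)
    out = out.reshape(B, Cout, *out_sp)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1, 1)

    def bwd(g):
        g_m = g.reshape(B, groups, Cout // groups, L)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if weight.requires_grad:
            gw = np.matmul(g_m, cols_m.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w_m.transpose(0, 2, 1)[None], g_m)  # (B,g,ck,L)
            gcols = gcols.reshape(B, Cin, k[0], k[1], k[2], *out_sp)
            gxp = np.zeros_like(xp)
            for a in range(k[0]):
                for b in range(k[1]):
                    for c in range(k[2]):
                        gxp[:, :,
                            a:a + s[0] * out_sp[0]:s[0],
                            b:b + s[1] * out_sp[1]:s[1],
                            c:c + s[2] * out_sp[2]:s[2]] += gcols[:, :, a, b, c]
            x._accumulate(gxp[:, :, p[0]:p[0] + D, p[1]:p[1] + H, p[2]:p[2] + W])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bwd)


def max_pool3d(x: Tensor, kernel=3, stride=2, padding=1) -> Tensor:
    k = _triple(kernel)
    s = _triple(stride)
    p = _triple(padding)
    B, C, D, H, W = x.data.shape
    out_sp = tuple(conv_out_size(n, kk, ss, pp) for n, kk, ss, pp in zip((D, H, W), k, s, p))
    pw = ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2]))
    xp = np.pad(x.data, pw, mode="constant", constant_values=-np.inf)
    cols = np.ascontiguousarray(_im2col(xp, k, s, out_sp))
    kk3 = k[0] * k[1] * k[2]
    flat = cols.reshape(B, C, kk3, *out_sp)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        od, oh, ow = np.meshgrid(*(np.arange(n) for n in out_sp), indexing="ij")
        a, rem = np.divmod(arg, k[1] * k[2])
        b, c = np.divmod(rem, k[2])
        di = od[None, None] * s[0] + a
        hi = oh[None, None] * s[1] + b
        wi = ow[None, None] * s[2] + c
        bi = np.arange(B)[:, None, None, None, None]
        ci = np.arange(C)[None, :, None, None, None]
        np.add.at(gxp, (bi, ci, di, hi, wi), g)
        x._accumulate(gxp[:, :, p[0]:p[0] + D, p[1]:p[1] + H, p[2]:p[2] + W])

    return Tensor._make(out, (x,), bwd)


def avg_pool3d_ceil(x: Tensor, factor: int = 2) -> Tensor:
    """Average pooling with kernel = stride = `factor`, ceil mode.

    Edge windows that extend past the volume average over their valid
    elements only (11 -> 6 along an axis, the last window holding one slab).
    """
    B, C, D, H, W = x.data.shape
    f = factor
    out_sp = tuple(-(-n // f) for n in (D, H, W))
    pad_sp = tuple(o * f - n for o, n in zip(out_sp, (D, H, W)))
    pw = ((0, 0), (0, 0), (0, pad_sp[0]), (0, pad_sp[1]), (0, pad_sp[2]))
    xp = np.pad(x.data, pw)
    r = xp.reshape(B, C, out_sp[0], f, out_sp[1], f, out_sp[2], f)
    sums = r.sum(axis=(3, 5, 7))
    ones = np.pad(np.ones((D, H, W), dtype=x.data.dtype), pw[2:])
    counts = ones.reshape(out_sp[0], f, out_sp[1], f, out_sp[2], f).sum(axis=(1, 3, 5))
    out = sums / counts

    def bwd(g):
        if not x.requires_grad:
            return
        gp = np.repeat(np.repeat(np.repeat(g / counts, f, axis=2), f, axis=3), f, axis=4)
        x._accumulate(gp[:, :, :D, :H, :W])

    return Tensor._make(out, (x,), bwd)


def _interp_matrix(n_src: int, n_dst: int, dtype=np.float64) -> np.ndarray:
    """1-D linear interpolation matrix under the half-pixel-center convention."""
    M = np.zeros((n_dst, n_src), dtype=dtype)
    if n_src == 1:
        M[:, 0] = 1.0
        return M
    scale = n_src / n_dst
    for i in range(n_dst):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_src - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_src - 1)
        w = src - lo
        M[i, lo] += 1.0 - w
        M[i, hi] += w
    return M


def resize_trilinear_np(data: np.ndarray, out_shape) -> np.ndarray:
    """Trilinear resampling of the trailing three axes of a numpy array."""
    *lead, D, H, W = data.shape
    Do, Ho, Wo = out_shape
    Md = _interp_matrix(D, Do, data.dtype)
    Mh = _interp_matrix(H, Ho, data.dtype)
    Mw = _interp_matrix(W, Wo, data.dtype)
    out = np.einsum("...dhw,ad->...ahw", data, Md, optimize=True)
    out = np.einsum("...dhw,ah->...daw", out, Mh, optimize=True)
    out = np.einsum("...dhw,aw->...dha", out, Mw, optimize=True)
    return out


def resize_trilinear(x: Tensor, out_shape) -> Tensor:
    D, H, W = x.data.shape[-3:]
    Do, Ho, Wo = out_shape
    if (D, H, W) == (Do, Ho, Wo):
        return x
    Md = _interp_matrix(D, Do, x.data.dtype)
    Mh = _interp_matrix(H, Ho, x.data.dtype)
    Mw = _interp_matrix(W, Wo, x.data.dtype)
    out = resize_trilinear_np(x.data, out_shape)

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.einsum("...ahw,ad->...dhw", g, Md, optimize=True)
        gx = np.einsum("...daw,ah->...dhw", gx, Mh, optimize=True)
        gx = np.einsum("...dha,aw->...dhw", gx, Mw, optimize=True)
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)


def unfold27(x: Tensor) -> Tensor:
    """Unfold the 3x3x3 neighborhood (zero padding 1) of a (B,C,D,H,W) field.

    Returns (B, C, 27, D, H, W); position index runs over the neighborhood
    offsets in lexicographic (dz, dy, dx) order.
    """
    B, C, D, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.empty((B, C, 27, D, H, W), dtype=x.data.dtype)
    idx = 0
    for a in range(3):
        for b in range(3):
            for c in range(3):
                out[:, :, idx] = xp[:, :, a:a + D, b:b + H, c:c + W]
                idx += 1

    def bwd(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        i = 0
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    gxp[:, :, a:a + D, b:b + H, c:c + W] += g[:, :, i]
                    i += 1
        x._accumulate(gxp[:, :, 1:1 + D, 1:1 + H, 1:1 + W])

    return Tensor._make(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, D, H, W) -> (B, C)."""
    return x.mean(axis=(2, 3, 4))
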