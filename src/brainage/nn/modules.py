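"""Layer abstractions over the autodiff engine.

Mirrors the familiar module/parameter idiom: a :class:`Module` owns named
parameters, buffers (non-trained state such as batch-norm running moments)
and submodules, exposes ``train()``/``eval()`` and a flat ``state_dict``.
Stochastic layers (dropout, stochastic depth, token pruning) draw from a
single generator shared across the module tree so a run is reproducible from
one integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _st

from .tensor import Tensor
from . import functional as F

_init_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the generator used for weight initialization."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


def kaiming_normal(shape, fan_in, dtype=np.float32):
    std = math.sqrt(2.0 / fan_in)
    return _init_rng.normal(0.0, std, size=shape).astype(dtype)


def trunc_normal(shape, std=0.02, dtype=np.float32):
    a, b = -2.0, 2.0  # clip at two standard deviations
    vals = _st.truncnorm.rvs(a, b, loc=0.0, scale=std, size=int(np.prod(shape)),
                             random_state=_init_rng)
    return vals.reshape(shape).astype(dtype)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_rng", np.random.default_rng(0))

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- modes & rng -------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def seed_stochastic(self, seed: int):
        """Share one seeded generator across every stochastic layer."""
        rng = np.random.default_rng(seed)
        for m in self.modules():
            object.__setattr__(m, "_rng", rng)
        return self

    # -- state -------------------------------------------------------------
    def state_dict(self):
        out = {}
        for n, p in self.named_parameters():
            out[n] = p.data.copy()
        for n, b in self.named_buffers():
            out["buffer:" + n] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for n, p in params.items():
            p.data = np.asarray(state[n]).copy()
        # buffers must be written back onto their owning module
        for mn, m in self._named_modules():
            for bn in list(m._buffers):
                key = "buffer:" + (mn + "." if mn else "") + bn
                if key in state:
                    m._set_buffer(bn, np.asarray(state[key]).copy())
        return self

    def _named_modules(self, prefix=""):
        yield prefix, self
        for mn, m in self._modules.items():
            yield from m._named_modules(prefix + mn if not prefix else prefix + "." + mn)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        k = kernel if isinstance(kernel, tuple) else (kernel,) * 3
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, k
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"conv channels {in_ch}->{out_ch} not divisible by groups={groups}")
        fan_in = (in_ch // groups) * k[0] * k[1] * k[2]
        self.weight = Tensor(kaiming_normal((out_ch, in_ch // groups, *k), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        if x.data.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.data.shape[1]}")
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, init_std=None):
        super().__init__()
        if init_std is None:
            w = kaiming_normal((in_f, out_f), in_f)
        else:
            w = trunc_normal((in_f, out_f), std=init_std)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm3d(Module):
    def __init__(self, ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum, self.ch = eps, momentum, ch
        self.weight = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(ch, np.float32))
        self.register_buffer("running_var", np.ones(ch, np.float32))
        self.frozen_stats = False  # hold running moments fixed (backbone freezing)

    def forward(self, x):
        sh = (1, self.ch, 1, 1, 1)
        if self.training and not self.frozen_stats:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3, 4), keepdims=True)
            n = x.data.size / self.ch
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._set_buffer("running_mean", ((1 - self.momentum) * self.running_mean
                                              + self.momentum * mu.data.reshape(-1)).astype(np.float32))
            self._set_buffer("running_var", ((1 - self.momentum) * self.running_var
                                             + self.momentum * unbiased).astype(np.float32))
        else:
            mu = Tensor(self.running_mean.reshape(sh).astype(x.data.dtype))
            var = Tensor(self.running_var.reshape(sh).astype(x.data.dtype))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(sh) + self.bias.reshape(sh)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.eps, self.dim = eps, dim
        self.weight = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p=0.1):
        super().__init__()
        self.p = p

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Dropout3d(Module):
    """Channel-wise volumetric dropout: whole feature channels are zeroed."""

    def __init__(self, p=0.1):
        super().__init__()
        self.p = p

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        B, C = x.data.shape[:2]
        mask = (self._rng.random((B, C, 1, 1, 1)) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample."""

    def __init__(self, p=0.0):
        super().__init__()
        self.p = p

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        shape = (x.data.shape[0],) + (1,) * (x.data.ndim - 1)
        mask = (self._rng.random(shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)
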