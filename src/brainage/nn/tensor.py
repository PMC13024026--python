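"""A small reverse-mode automatic differentiation engine on numpy arrays.

The engine implements exactly the primitives the volumetric networks in this
package need (broadcast arithmetic, batched matmul, reductions, slicing,
concatenation, padding and elementwise nonlinearities).  Gradients are
accumulated by walking the recorded operation graph in reverse topological
order.  Arrays keep whatever float dtype they are given, which lets the test
suite run finite-difference checks in float64 while models train in float32.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special as _sc


def _as_array(x, like=None):
    if isinstance(x, Tensor):
        return x.data
    dtype = like.dtype if like is not None else np.float32
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the recorded graph
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph helpers -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        track = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=track, parents=parents if track else (),
                      backward=backward if track else None)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return (self ** -1.0) * other

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for ax in axes:
                n *= self.data.shape[ax]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = _sc.expit(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def gelu(self):
        """Exact (erf-form) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _sc.erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def bwd(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accumulate(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        out_data = np.abs(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        return Tensor._make(out_data, (self,), bwd)

    def softmax(self, axis=-1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift, no grad
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def pad(t: Tensor, pad_width, value: float = 0.0) -> Tensor:
    """Constant-pad; pad_width follows numpy's ((before, after), ...) form."""
    out_data = np.pad(t.data, pad_width, mode="constant", constant_values=value)
    crop = tuple(slice(b, out_data.shape[i] - a) for i, (b, a) in enumerate(pad_width))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[crop])

    return Tensor._make(out_data, (t,), bwd)
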