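"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a small Transformer encoder: broadcast-aware
elementwise arithmetic, (batched) matrix products, reductions, reshaping,
row gathering for embeddings, numerically stable softmax/log-softmax, GELU,
and an Adam optimizer.  Gradients flow through a dynamically built tape and
are verified against central finite differences in the test suite.

Arrays keep the dtype they are given (models use float32; gradient checks
use float64).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[Array], None] | None = None):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: Array) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):  # scalars must not promote dtype
            out = Tensor(self.data + np.asarray(other, dtype=self.data.dtype),
                         _parents=(self,))

            def back(g: Array) -> None:
                self._accum(g)
            out._backward = back
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def back(g: Array) -> None:
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            c = float(other)
            out = Tensor(self.data * np.asarray(c, dtype=self.data.dtype),
                         _parents=(self,))

            def back(g: Array) -> None:
                self._accum(g * c)
            out._backward = back
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def back(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = back
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def back(g: Array) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = back
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g.reshape(self.data.shape))
        out._backward = back
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g.transpose(*inv))
        out._backward = back
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back(g: Array) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g * out.data)
        out._backward = back
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g / self.data)
        out._backward = back
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def back(g: Array) -> None:
            self._accum(g * (1.0 - out.data ** 2))
        out._backward = back
        return out


def take_rows(t: Tensor, indices: Sequence[int] | Array) -> Tensor:
    """Select rows along axis 0 (embedding lookup / position gather)."""
    idx = np.asarray(indices, dtype=np.intp)
    out = Tensor(t.data[idx], _parents=(t,))

    def back(g: Array) -> None:
        acc = np.zeros_like(t.data)
        np.add.at(acc, idx, g)
        t._accum(acc)
    out._backward = back
    return out


def gather_last(t: Tensor, indices: Sequence[int] | Array) -> Tensor:
    """out[i] = t[i, indices[i]] for a 2-D tensor."""
    idx = np.asarray(indices, dtype=np.intp)
    rows = np.arange(t.data.shape[0])
    out = Tensor(t.data[rows, idx], _parents=(t,))

    def back(g: Array) -> None:
        acc = np.zeros_like(t.data)
        acc[rows, idx] = g
        t._accum(acc)
    out._backward = back
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _parents=(t,))

    def back(g: Array) -> None:
        t._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
    out._backward = back
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, _parents=(t,))
    s = np.exp(out.data)

    def back(g: Array) -> None:
        t._accum(g - s * g.sum(axis=axis, keepdims=True))
    out._backward = back
    return out


_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(t: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = t.data
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    out = Tensor(x * phi, _parents=(t,))

    def back(g: Array) -> None:
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        t._accum(g * (phi + x * pdf))
    out._backward = back
    return out


def dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return t
    u = rng.random(t.data.shape, dtype=np.float32)
    keep = (u >= rate).astype(t.data.dtype)
    keep *= np.asarray(1.0 / (1.0 - rate), dtype=t.data.dtype)
    return t * Tensor(keep)


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalize over the last axis, then scale and shift (fused op)."""
    x = t.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.dtype))
    xn = xc * inv
    out = Tensor(xn * gain.data + bias.data, _parents=(t, gain, bias))

    def back(g: Array) -> None:
        if gain.requires_grad:
            gain._accum((g * xn).reshape(-1, x.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, x.shape[-1]).sum(axis=0))
        if t.requires_grad:
            gxn = g * gain.data
            t._accum((gxn - xn * (gxn * xn).mean(axis=-1, keepdims=True)
                      - gxn.mean(axis=-1, keepdims=True)) * inv)
    out._backward = back
    return out


def attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    """Fused scaled-dot-product attention over (heads, length, d_head)."""
    qd, kd, vd = q.data, k.data, v.data
    att = qd @ kd.swapaxes(-1, -2)
    att *= np.asarray(scale, dtype=att.dtype)
    att -= att.max(axis=-1, keepdims=True)
    np.exp(att, out=att)
    att /= att.sum(axis=-1, keepdims=True)
    out = Tensor(att @ vd, _parents=(q, k, v))

    def back(g: Array) -> None:
        if v.requires_grad:
            v._accum(att.swapaxes(-1, -2) @ g)
        g_s = g @ vd.swapaxes(-1, -2)
        g_s -= (g_s * att).sum(axis=-1, keepdims=True)
        g_s *= att
        g_s *= np.asarray(scale, dtype=g_s.dtype)
        if q.requires_grad:
            q._accum(g_s @ kd)
        if k.requires_grad:
            k._accum(g_s.swapaxes(-1, -2) @ qd)
    out._backward = back
    return out


class Adam:
    """Adam with the standard bias correction; per-step learning rate."""

    def __init__(self, params: dict[str, Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            p.data = p.data - lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = state["m"]
        self.v = state["v"]
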