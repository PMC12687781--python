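"""A compact reverse-mode automatic-differentiation engine on numpy.

The denoiser network needs triangle attention, triangle multiplicative
updates, adaptive layer normalization and an Adam training loop.  This
module provides the minimal tensor machinery for that: a :class:`Tensor`
with a dynamic tape, broadcasting-aware elementwise ops, reductions, two-
operand einsum (whose backward is itself an einsum), shape ops, composed
softmax/layer-norm, parameter containers and Adam.

Design notes
------------
* All data is float32; einsum calls use ``optimize=True`` so contractions
  dispatch to BLAS where possible.
* ``einsum`` requires explicit subscripts (no ellipsis) and every index of
  each operand to appear in the output or the other operand — true for all
  contractions used here and checked lazily by numpy.
* Gradients are verified against central finite differences in the test
  suite; this engine is intentionally small, not general.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "layer_norm_op",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "einsum",
    "concat",
    "softmax",
    "Adam",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode).

    Inside the context, ops produce leaf tensors with no parents, so large
    intermediates are freed as soon as they go out of scope.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a backward tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "_owns_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._owns_grad = False
        if _GRAD_ENABLED:
            self._parents = parents
            self._backward = backward
            self.requires_grad = requires_grad or any(p._needs_grad() for p in parents)
        else:
            self._parents = ()
            self._backward = None
            self.requires_grad = requires_grad

    def _needs_grad(self) -> bool:
        return self.requires_grad

    def _set_backward(self, fn: Callable[[np.ndarray], None]) -> None:
        # attaching the closure only when needed keeps no-grad mode free of
        # references that would pin large intermediates in memory
        if self.requires_grad:
            self._backward = fn

    # -- graph ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        self._owns_grad = False
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is held by reference (never mutated); a second
        # contribution allocates, after which accumulation is in place
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad
            self._owns_grad = False
        elif self._owns_grad:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._owns_grad = True

    def zero_grad(self) -> None:
        self.grad = None
        self._owns_grad = False

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- shape ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._set_backward(lambda g: self._accum(g.reshape(old)))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._set_backward(lambda g: self._accum(g.transpose(inv)))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], (self,))

        def back(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._set_backward(back)
        return out

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._set_backward(back)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._set_backward(lambda g: self._accum(-g))
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._set_backward(back)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._set_backward(back)
        return out

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, (self,))
        out._set_backward(lambda g: self._accum(g * p * self.data ** (p - 1)))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._set_backward(lambda g: self._accum(g * y))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._set_backward(lambda g: self._accum(g / self.data))
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._set_backward(lambda g: self._accum(g * (1.0 - y * y)))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._set_backward(lambda g: self._accum(g * y * (1.0 - y)))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._set_backward(lambda g: self._accum(g * mask))
        return out

    def clip_max(self, v: float) -> "Tensor":
        """Elementwise min(x, v); gradient is zero where clipped."""
        mask = self.data < v
        out = Tensor(np.minimum(self.data, v), (self,))
        out._set_backward(lambda g: self._accum(g * mask))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % len(shape) for a in axes)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, shape))

        out._set_backward(back)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


_EINSUM_PATHS: dict = {}


def _einsum_cached(spec: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """np.einsum with the contraction path cached per (spec, shapes)."""
    key = (spec, x.shape, y.shape)
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(spec, x, y, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(spec, x, y, optimize=path)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with an einsum backward pass."""
    lhs, out_spec = spec.split("->")
    sa, sb = lhs.split(",")
    out = Tensor(_einsum_cached(spec, a.data, b.data), (a, b))

    def back(g):
        a._accum(
            _unbroadcast(_einsum_cached(f"{out_spec},{sb}->{sa}", g, b.data), a.data.shape)
        )
        b._accum(
            _unbroadcast(_einsum_cached(f"{out_spec},{sa}->{sb}", g, a.data), b.data.shape)
        )

    out._set_backward(back)
    return out


def layer_norm_op(
    x: Tensor,
    gain: Tensor | None = None,
    bias: Tensor | None = None,
    eps: float = 1e-5,
) -> Tensor:
    """Fused layer normalization over the last axis with analytic backward."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y_hat = xc * inv
    out_data = y_hat
    if gain is not None:
        out_data = out_data * gain.data + bias.data
    parents = (x,) if gain is None else (x, gain, bias)
    out = Tensor(out_data, parents)

    def back(g):
        if gain is not None:
            gy = g * gain.data
            axes = tuple(range(g.ndim - 1))
            gain._accum(_unbroadcast((g * y_hat).sum(axis=axes), gain.data.shape))
            bias._accum(_unbroadcast(g.sum(axis=axes), bias.data.shape))
        else:
            gy = g
        m1 = gy.mean(axis=-1, keepdims=True)
        m2 = (gy * y_hat).mean(axis=-1, keepdims=True)
        x._accum(inv * (gy - m1 - y_hat * m2))

    out._set_backward(back)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._set_backward(back)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax composed of primitive ops."""
    shift = x - x.data.max(axis=axis, keepdims=True)  # detached max
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class with recursive parameter discovery and state (de)serialization."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        found: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                found.append((full, value))
            elif isinstance(value, Module):
                found.extend(value.named_parameters(prefix=f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        found.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        found.append((f"{full}.{i}", item))
        return found

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for parameters: {sorted(missing)}")
        for name, p in params.items():
            value = np.asarray(state[name], dtype=np.float32)
            if value.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = value.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """Affine map on the last axis.  ``init='zero'`` gives identity-start heads."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        init: str = "lecun",
        rng: np.random.Generator | None = None,
        bias_init: float = 0.0,
    ):
        rng = rng or np.random.default_rng(0)
        if init == "zero":
            w = np.zeros((in_features, out_features))
        elif init == "lecun":
            w = rng.normal(0.0, 1.0 / math.sqrt(in_features), (in_features, out_features))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(out_features, bias_init)) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape((-1, self.in_features))
        y = einsum("ni,io->no", flat, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(lead + (self.out_features,))


class LayerNorm(Module):
    """Layer normalization over the last axis with learnable gain/bias."""

    def __init__(self, n_features: int, eps: float = 1e-5, elementwise: bool = True):
        self.gain = Parameter(np.ones(n_features)) if elementwise else None
        self.bias = Parameter(np.zeros(n_features)) if elementwise else None
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm_op(x, self.gain, self.bias, eps=self.eps)


class Adam:
    """Adam optimizer over an explicit parameter list.

    ``clip_norm`` rescales the global gradient norm before each update —
    single-sample training on diverse structures has heavy-tailed
    gradients, and clipping keeps rare large steps from undoing progress.
    """

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
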