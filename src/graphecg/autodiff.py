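"""Minimal reverse-mode automatic differentiation on numpy arrays.

The hybrid lead-graph / transformer classifier in :mod:`graphecg.model` is
small (a few tens of thousands of parameters) and runs on CPU, so rather than
depending on a deep-learning framework the package carries a compact tape
based autodiff engine: a :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` walks the tape in
reverse topological order accumulating gradients.

Only the operations the model needs are provided (broadcast arithmetic,
batched ``matmul``, reductions, ``relu``/``exp``/``log``/``sqrt``, shape
manipulation) plus the composites ``softmax`` and ``layer_norm``.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "softmax", "log_softmax", "layer_norm", "mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- tape machinery -------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                t._accumulate_into(grads, g)
            else:
                t.grad = g if t.grad is None else t.grad + g

    def _accumulate_into(self, grads: dict[int, np.ndarray], g: np.ndarray) -> None:
        # _backward fills parent gradients through the closure, using `grads`
        self._backward(g, grads)  # type: ignore[call-arg]

    @staticmethod
    def _add_grad(grads: dict[int, np.ndarray], t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t._backward is None:  # leaf
            t.grad = g if t.grad is None else t.grad + g
            # leaves also flow through dict so interior reuse works
        key = id(t)
        if t._backward is not None:
            grads[key] = g if key not in grads else grads[key] + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g, grads):
            Tensor._add_grad(grads, a, _unbroadcast(g, a.shape))
            Tensor._add_grad(grads, b, _unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g, grads):
            Tensor._add_grad(grads, a, -g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g, grads):
            Tensor._add_grad(grads, a, _unbroadcast(g * b.data, a.shape))
            Tensor._add_grad(grads, b, _unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g, grads):
            Tensor._add_grad(grads, a, _unbroadcast(g / b.data, a.shape))
            Tensor._add_grad(grads, b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        a, b = self, other
        # 1-D operands follow the numpy promotion rules via reshape
        if a.ndim == 1 and b.ndim == 1:
            return (a * b).sum()
        if a.ndim == 1:
            out = a.reshape(1, -1) @ b
            return out.reshape(b.shape[:-2] + (b.shape[-1],))
        if b.ndim == 1:
            out = a @ b.reshape(-1, 1)
            return out.reshape(a.shape[:-1])

        def backward(g, grads):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            Tensor._add_grad(grads, a, _unbroadcast(ga, a.shape))
            Tensor._add_grad(grads, b, _unbroadcast(gb, b.shape))

        return self._make(a.data @ b.data, (a, b), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        e = float(exponent)

        def backward(g, grads):
            Tensor._add_grad(grads, a, g * e * a.data ** (e - 1.0))

        return self._make(a.data ** e, (a,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g, grads):
            Tensor._add_grad(grads, a, g * mask)

        return self._make(a.data * mask, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g, grads):
            Tensor._add_grad(grads, a, g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g, grads):
            Tensor._add_grad(grads, a, g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g, grads):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            Tensor._add_grad(grads, a, np.broadcast_to(g, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g, grads):
            Tensor._add_grad(grads, a, g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def backward(g, grads):
            Tensor._add_grad(grads, a, np.swapaxes(g, ax1, ax2))

        return self._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def transpose(self, *axes) -> "Tensor":
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def backward(g, grads):
            Tensor._add_grad(grads, a, g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)


def mean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    """Arithmetic mean as a differentiable composite of sum and divide."""
    if axis is None:
        n = t.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= t.shape[ax]
    return t.sum(axis=axis, keepdims=keepdims) / float(n)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is treated as a constant."""
    shift = Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(t.data, axis=axis, keepdims=True))
    z = t - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(t: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable scale and shift."""
    mu = mean(t, axis=-1, keepdims=True)
    centered = t - mu
    var = mean(centered * centered, axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gamma + beta
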