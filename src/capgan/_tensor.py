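"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (desk-scale grayscale GANs), so a
vectorised numpy tape is entirely adequate: every operation records a
backward closure that accumulates gradients into its parents.  Only the
operations the generator/discriminator assemblies actually need are
implemented.  Gradients are checked against central finite differences in
the test suite.

Module-level helpers (``exp``, ``tsum`` ...) dispatch on input type so the
capsule mathematics can be written once and run either on plain ndarrays
(analysis, oracles) or on :class:`Tensor` (training).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "make_op", "default_dtype"]

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


class default_dtype:
    """Context manager setting the tape's working precision.

    Training runs in float32 for speed; analysis and gradient checks keep
    the float64 default.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global _DEFAULT_DTYPE
        self._prev = _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # make ndarray <op> Tensor defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep with routing unrolled)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = make_op(self.data + o.data, (self, o))
        if out.requires_grad:
            def _bw():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.shape))
                if o.requires_grad:
                    o._accum(_unbroadcast(out.grad, o.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = make_op(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-o)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = make_op(self.data * o.data, (self, o))
        if out.requires_grad:
            def _bw():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * o.data, self.shape))
                if o.requires_grad:
                    o._accum(_unbroadcast(out.grad * self.data, o.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = make_op(self.data / o.data, (self, o))
        if out.requires_grad:
            def _bw():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad / o.data, self.shape))
                if o.requires_grad:
                    o._accum(_unbroadcast(-out.grad * self.data / (o.data ** 2), o.shape))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = make_op(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = make_op(np.matmul(self.data, o.data), (self, o))
        if out.requires_grad:
            def _bw():
                g = out.grad
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(o.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.shape))
                if o.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    o._accum(_unbroadcast(gb, o.shape))
            out._backward = _bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = make_op(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = make_op(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def transpose(self, axes):
        out = make_op(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda: self._accum(out.grad.transpose(inv))
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = make_op(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = make_op(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def sqrt(self):
        out = make_op(np.sqrt(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * 0.5 / out.data)
        return out

    def tanh(self):
        out = make_op(np.tanh(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = make_op(1.0 / (1.0 + np.exp(-self.data)), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = make_op(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda: self._accum(out.grad * mask)
        return out

    def leaky_relu(self, slope: float):
        """Fused leaky rectifier: x if x >= 0 else slope * x."""
        neg = self.data < 0
        out = make_op(np.where(neg, slope * self.data, self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(np.where(neg, slope * out.grad, out.grad))
        return out

    def clip(self, lo: float, hi: float):
        out = make_op(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda: self._accum(out.grad * mask)
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def make_op(data: np.ndarray, parents: tuple) -> Tensor:
    """Create an op-output tensor tracking only grad-requiring Tensor parents."""
    out = Tensor(data)
    if _GRAD_ENABLED:
        tracked = tuple(p for p in parents if isinstance(p, Tensor) and p.requires_grad)
        if tracked:
            out.requires_grad = True
            out._parents = tracked
    return out


# ---------------------------------------------------------------------------
# dual-dispatch helpers: work on ndarray and Tensor alike
# ---------------------------------------------------------------------------

def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def sigmoid(x):
    return x.sigmoid() if isinstance(x, Tensor) else 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(np.asarray(x, float), 0.0)


def clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(np.asarray(x, float), lo, hi)


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.asarray(x, float).sum(axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.asarray(x, float).mean(axis=axis, keepdims=keepdims)


def reshape(x, shape):
    if isinstance(x, Tensor):
        return x.reshape(shape)
    return np.asarray(x, float).reshape(shape)


def raw(x) -> np.ndarray:
    """Underlying ndarray of either an ndarray or a Tensor."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)
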