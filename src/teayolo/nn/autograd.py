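"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is a tape of :class:`Tensor` nodes.  Each operation records its
parent tensors together with a closure that maps the incoming gradient to a
gradient contribution for that parent; :meth:`Tensor.backward` runs the tape
in reverse topological order.  Only the primitives the detector needs are
provided — elementwise arithmetic, broadcasting reductions, matmul, the
activations used by the blocks, and the structural ops (reshape, transpose,
slicing, concatenation).  Convolution and pooling primitives live in
:mod:`teayolo.nn.functional`.

Float32 is the working precision; tensors built from float64 input keep
float64, which the finite-difference tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


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


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _coerce(data):
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __array_priority__ = 100.0
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = _coerce(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(_parents) if self.requires_grad else ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents):
        parents = [(t, fn) for t, fn in parents if t.requires_grad]
        req = bool(parents) and _GRAD_ENABLED
        return Tensor(data, requires_grad=req, _parents=parents if req else ())

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        # topological order over the tape
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))

        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy() if node._parents == () else g
            else:
                node.grad = node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                if contrib is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib
        # leaves keep .grad; interior nodes also keep it (cheap, occasionally useful)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self.data + other.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data * b.data, [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data / b.data, [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
        ])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** p
        return Tensor._make(out, [(self, lambda g: g * p * self.data ** (p - 1))])

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g * 0.5 / out)])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def arctan(self):
        return Tensor._make(np.arctan(self.data),
                            [(self, lambda g: g / (1.0 + self.data ** 2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, [(self, lambda g: g * out * (1.0 - out))])

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * s
        return Tensor._make(out, [(self, lambda g: g * (s + self.data * s * (1.0 - s)))])

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def grad_fn(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            return g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner)

        return Tensor._make(out, [(self, grad_fn)])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def abs(self):
        s = np.sign(self.data)
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * s)])

    def maximum(self, other):
        other = as_tensor(other)
        mask = self.data >= other.data
        out = np.where(mask, self.data, other.data)
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g * mask, self.data.shape)),
            (other, lambda g: _unbroadcast(g * (~mask), other.data.shape)),
        ])

    def minimum(self, other):
        other = as_tensor(other)
        mask = self.data <= other.data
        out = np.where(mask, self.data, other.data)
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g * mask, self.data.shape)),
            (other, lambda g: _unbroadcast(g * (~mask), other.data.shape)),
        ])

    def clamp(self, lo=None, hi=None):
        out = self
        if lo is not None:
            out = out.maximum(Tensor(np.full((), lo, dtype=self.dtype)))
        if hi is not None:
            out = out.minimum(Tensor(np.full((), hi, dtype=self.dtype)))
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, [(self, grad_fn)])

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            out_k = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == out_k)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape) * mask

        return Tensor._make(out, [(self, grad_fn)])

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        del z
        return e / e.sum(axis=axis, keepdims=True)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def grad_a(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            return _unbroadcast(ga, a.data.shape)

        def grad_b(g):
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(gb, b.data.shape)

        return Tensor._make(out, [(a, grad_a), (b, grad_b)])

    __matmul__ = matmul

    # -- structural -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape),
                            [(self, lambda g: g.reshape(old))])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes),
                            [(self, lambda g: g.transpose(inv))])

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out = self.data[idx]

        def grad_fn(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor._make(out, [(self, grad_fn)])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        n = t.data.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offset, offset + n)
        sl = tuple(sl)
        parents.append((t, (lambda s: lambda g: g[s])(sl)))
        offset += n
    return Tensor._make(out, parents)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        parents.append((t, (lambda j: lambda g: np.take(g, j, axis=axis))(i)))
    return Tensor._make(out, parents)
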