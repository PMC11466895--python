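"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: float64 tensors, broadcasting arithmetic,
2-D matmul, elementwise nonlinearities, reductions, concatenation,
integer-array gathering and row tiling/repetition.  This covers the fully
connected networks (encoder, deformation decoder, inverse-deformation
net), the deformation regularizers and the KL term.  Operations whose
gradients are easier to derive by hand (the Fourier-space image-formation
loss) plug in through :func:`custom`.
"""
from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._vjp = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._vjp is None:
                t.grad = g if t.grad is None else t.grad + g
            if t._vjp is not None:
                for p, pg in zip(t._parents, t._vjp(g)):
                    if pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
                    # leaves keep their grad attribute up to date
                    if p.requires_grad and p._vjp is None and not p._parents:
                        pass

    # operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracing(*ts) -> bool:
    return _grad_enabled and any(
        t.requires_grad or t._parents for t in ts if isinstance(t, Tensor)
    )


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if _tracing(*parents):
        out._parents = tuple(parents)
        out._vjp = vjp
        out.requires_grad = False
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- primitive ops ------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
        ),
    )


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def reshape(a, shape):
    a = as_tensor(a)
    old = a.data.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    shape = a.data.shape

    def vjp(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, shape).copy(),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def elu(a, alpha: float = 1.0):
    a = as_tensor(a)
    pos = a.data > 0
    out = np.where(pos, a.data, alpha * np.expm1(np.minimum(a.data, 0.0)))
    return _node(out, (a,), lambda g: (g * np.where(pos, 1.0, out + alpha),))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a):
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sin(a):
    a = as_tensor(a)
    return _node(np.sin(a.data), (a,), lambda g: (g * np.cos(a.data),))


def cos(a):
    a = as_tensor(a)
    return _node(np.cos(a.data), (a,), lambda g: (-g * np.sin(a.data),))


def sqrt(a, eps: float = 0.0):
    a = as_tensor(a)
    out = np.sqrt(a.data + eps)
    return _node(out, (a,), lambda g: (g * 0.5 / np.maximum(out, 1e-300),))


def square(a):
    a = as_tensor(a)
    return _node(a.data ** 2, (a,), lambda g: (2.0 * g * a.data,))


def take(a, idx, axis: int = 0):
    """Gather rows (or slices along `axis`) by an integer index array."""
    a = as_tensor(a)
    idx = np.asarray(idx)
    shape = a.data.shape

    def vjp(g):
        out = np.zeros(shape, dtype=np.float64)
        if axis == 0:
            np.add.at(out, idx, g)
        else:
            sl = [slice(None)] * a.data.ndim
            mv = np.moveaxis(out, axis, 0)
            np.add.at(mv, idx, np.moveaxis(g, axis, 0))
        return (out,)

    return _node(np.take(a.data, idx, axis=axis), (a,), vjp)


def tile_rows(a, reps: int):
    """(M, F) -> (reps*M, F), block-repeat [a; a; ...]."""
    a = as_tensor(a)
    m = a.data.shape[0]

    def vjp(g):
        return (g.reshape(reps, m, *a.data.shape[1:]).sum(axis=0),)

    return _node(np.tile(a.data, (reps,) + (1,) * (a.data.ndim - 1)), (a,), vjp)


def repeat_rows(a, reps: int):
    """(B, F) -> (B*reps, F), each row repeated `reps` times contiguously."""
    a = as_tensor(a)
    b = a.data.shape[0]

    def vjp(g):
        return (g.reshape(b, reps, *a.data.shape[1:]).sum(axis=1),)

    return _node(np.repeat(a.data, reps, axis=0), (a,), vjp)


def softmax(a, axis: int = 0):
    a = as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return _node(s, (a,), vjp)


def custom(data, parents, vjp) -> Tensor:
    """Create a node with a hand-written vector-Jacobian product.

    `vjp(grad_out)` must return one gradient (or None) per parent.
    """
    return _node(data, [as_tensor(p) for p in parents], vjp)


def norm_rows(a, eps: float = 1e-12):
    """Euclidean norm along the last axis."""
    return sqrt(tsum(square(a), axis=-1), eps=eps)
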