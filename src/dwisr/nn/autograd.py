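"""Minimal reverse-mode automatic differentiation on numpy arrays.

Design notes
------------
Every primitive's backward pass is itself expressed in terms of these same
primitives, so gradients are ordinary graph nodes and can be differentiated
again.  This is what makes the WGAN gradient-penalty term trainable: the
penalty depends on ``grad(D(x_hat), x_hat)`` and its parameter gradient
requires backpropagating *through* that gradient (double backprop).

The primitive set is deliberately small: elementwise arithmetic, powers,
log/exp, reductions, broadcasting, reshape/transpose, 2-D matmul, and a
gather/scatter pair (``take``/``scatter_add``).  Convolutions, padding,
pixel shuffles and upsampling are all built from gather/scatter plus matmul
(see :mod:`dwisr.nn.functional`), so the closure under differentiation holds
for the whole network stack.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def set_grad_enabled(mode: bool):
    _GRAD_ENABLED.append(bool(mode))
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def no_grad():
    return set_grad_enabled(False)


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A numpy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.parents: tuple = ()
        self.vjp = None

    # -- conveniences -------------------------------------------------
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

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out.parents = tuple(parents)
        out.vjp = vjp
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return reshape(g, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: (neg(g),))


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _make(
        a.data**p,
        (a,),
        lambda g: (mul(g, mul(Tensor(np.asarray(p)), power(a, p - 1.0))),),
    )


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, out),)
    return out


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    shape = a.shape

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * len(shape)), shape),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, shape),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def scalar_like(value: float, t: Tensor) -> Tensor:
    """A 0-d constant matching the dtype of ``t`` (avoids float64 promotion)."""
    dtype = t.dtype if np.issubdtype(t.dtype, np.floating) else np.float64
    return Tensor(np.asarray(value, dtype=dtype))


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), scalar_like(1.0 / n, a))


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    src = a.shape
    return _make(
        np.broadcast_to(a.data, shape),
        (a,),
        lambda g: (_unbroadcast(g, src),),
    )


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    src = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, src),))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul primitive is 2-D only")
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b, (1, 0))), matmul(transpose(a, (1, 0)), g)),
    )


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather from the flattened ``a`` at integer index array ``idx``."""
    a = _as_tensor(a)
    size = a.size
    shape = a.shape
    return _make(
        a.data.reshape(-1)[idx],
        (a,),
        lambda g: (reshape(scatter_add(g, idx, size), shape),),
    )


def scatter_add(a: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Scatter-add ``a`` (any shape) into a flat zero vector of ``size``.

    ``idx`` must have the same shape as ``a``; duplicate indices accumulate.
    """
    a = _as_tensor(a)
    if idx.shape != a.shape:
        raise ValueError("scatter_add index must match input shape")
    # bincount is much faster than np.add.at for large duplicate-index scatters
    out = np.bincount(idx.reshape(-1), weights=a.data.reshape(-1), minlength=size)
    out = out.astype(a.dtype, copy=False)
    return _make(out, (a,), lambda g: (take(g, idx),))


def cast(a: Tensor, dtype) -> Tensor:
    """Dtype cast; the gradient is cast back to the source dtype."""
    a = _as_tensor(a)
    src = a.dtype
    return _make(a.data.astype(dtype), (a,), lambda g: (cast(g, src),))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    # derivative is piecewise constant, so a constant mask is exact (a.e.)
    # and its second derivative is zero — safe under double backprop.
    mask = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return mul(a, Tensor(mask))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _topo(output: Tensor):
    order, seen = [], set()
    stack = [(output, False)]
    while stack:
        node, done = stack.pop()
        if id(node) in seen:
            continue
        if done:
            seen.add(id(node))
            order.append(node)
            continue
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and may be differentiated again.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    inputs = list(inputs)
    grads = {id(output): Tensor(np.ones_like(output.data))}
    with set_grad_enabled(create_graph):
        for node in reversed(_topo(output)):
            g = grads.pop(id(node), None)
            if g is None or node.vjp is None:
                if g is not None:
                    grads[id(node)] = g
                continue
            parent_grads = node.vjp(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
            grads[id(node)] = g
    return [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]
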