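"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small graph networks with a Wasserstein critic whose
gradient-penalty term requires differentiating through a gradient.  To make
that possible every backward rule here is itself expressed with ``Tensor``
operations, so the output of :func:`grad` is again a differentiable node and
``grad(grad(...))`` is well defined (double backprop).

Only the operations the models need are implemented; all arrays are
``float64``.  This is a deliberately small engine, not a general framework.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "power",
    "sum_",
    "mean",
    "max_",
    "reshape",
    "swapaxes",
    "broadcast_to",
    "getitem",
    "concat",
    "leaky_relu",
    "detach",
    "softmax",
    "Adam",
]


class Tensor:
    """A numpy array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data, parents, vjps) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjps=vjps)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    shape = tuple(shape)
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data + b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g, a.data.shape),
            lambda g: _unbroadcast(g, b.data.shape),
        ),
    )


def neg(a) -> Tensor:
    a = _t(a)
    return _op(-a.data, (a,), (lambda g: neg(g),))


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(mul(g, b), a.data.shape),
            lambda g: _unbroadcast(mul(g, a), b.data.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data / b.data,
        (a, b),
        (
            lambda g: _unbroadcast(div(g, b), a.data.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    """Elementwise ``a ** p`` for a python scalar exponent."""
    a = _t(a)
    p = float(p)
    return _op(
        a.data ** p,
        (a,),
        (lambda g: mul(g, mul(power(a, p - 1.0), p)),),
    )


def matmul(a, b) -> Tensor:
    """Matrix product; operands must be >= 2-D (batched via broadcasting)."""
    a, b = _t(a), _t(b)
    return _op(
        np.matmul(a.data, b.data),
        (a, b),
        (
            lambda g: _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.data.shape),
            lambda g: _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.data.shape),
        ),
    )


def exp(a) -> Tensor:
    a = _t(a)
    out = _op(np.exp(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = _t(a)
    return _op(np.log(a.data), (a,), (lambda g: div(g, a),))


def sqrt(a) -> Tensor:
    a = _t(a)
    out = _op(np.sqrt(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: div(g, mul(out, 2.0)),)
    return out


def tanh(a) -> Tensor:
    a = _t(a)
    out = _op(np.tanh(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, sub(1.0, mul(out, out))),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _t(a)
    mask = np.where(a.data > 0.0, 1.0, slope)
    return _op(a.data * mask, (a,), (lambda g: mul(g, Tensor(mask)),))


def detach(a) -> Tensor:
    return Tensor(_t(a).data.copy())


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _t(a)
    old = a.data.shape
    return _op(a.data.reshape(shape), (a,), (lambda g: reshape(g, old),))


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _t(a)
    return _op(np.swapaxes(a.data, ax1, ax2), (a,), (lambda g: swapaxes(g, ax1, ax2),))


def broadcast_to(a, shape) -> Tensor:
    a = _t(a)
    return _op(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        (lambda g: _unbroadcast(g, a.data.shape),),
    )


def getitem(a, idx) -> Tensor:
    a = _t(a)
    shape = a.data.shape
    return _op(a.data[idx], (a,), (lambda g: _scatter(g, idx, shape),))


def _scatter(g: Tensor, idx, shape) -> Tensor:
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return _op(out, (g,), (lambda h: getitem(h, idx),))


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    ts = [_t(t) for t in tensors]
    datas = [t.data for t in ts]
    out = np.concatenate(datas, axis=axis)
    ax = axis if axis >= 0 else out.ndim + axis
    offsets = np.cumsum([0] + [d.shape[ax] for d in datas])

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[ax] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: getitem(g, sl)

    return _op(out, tuple(ts), tuple(make_vjp(i) for i in range(len(ts))))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _expand_reduced(g: Tensor, shape, axis, keepdims: bool) -> Tensor:
    """Broadcast a reduced gradient back to ``shape``."""
    if axis is None:
        return broadcast_to(reshape(g, (1,) * len(shape)), shape)
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    axes = tuple(a % len(shape) for a in axes)
    if not keepdims:
        kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
        g = reshape(g, kshape)
    return broadcast_to(g, shape)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _t(a)
    shape = a.data.shape
    return _op(
        np.sum(a.data, axis=axis, keepdims=keepdims),
        (a,),
        (lambda g: _expand_reduced(g, shape, axis, keepdims),),
    )


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _t(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax % a.data.ndim] for ax in ((axis,) if isinstance(axis, int) else axis)]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def max_(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; gradient routed to the (first) argmax entries."""
    a = _t(a)
    shape = a.data.shape
    idx = np.argmax(a.data, axis=axis)
    mask = np.zeros_like(a.data)
    np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
    out = np.max(a.data, axis=axis, keepdims=keepdims)
    return _op(
        out,
        (a,),
        (lambda g: mul(_expand_reduced(g, shape, axis, keepdims), Tensor(mask)),),
    )


def softmax(a, axis: int = -1) -> Tensor:
    a = _t(a)
    # shift by a constant max for stability; softmax is shift-invariant
    shift = Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(sub(a, shift))
    return div(e, sum_(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# autodiff driver
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs: Iterable[Tensor], seed: Tensor | None = None):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    Returns differentiable ``Tensor`` gradients (second-order works).  ``seed``
    defaults to ones of the output's shape, i.e. the gradient of
    ``sum(output)``.
    """
    inputs = list(inputs)
    if not output.requires_grad:
        return [Tensor(np.zeros_like(i.data)) for i in inputs]

    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {
        id(output): seed if seed is not None else Tensor(np.ones_like(output.data))
    }
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)

    return [
        grads.get(id(i), Tensor(np.zeros_like(i.data))) for i in inputs
    ]


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam on a fixed list of parameter tensors (updates in place)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor | np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
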