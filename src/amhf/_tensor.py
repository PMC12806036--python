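"""Reverse-mode automatic differentiation on numpy arrays.

The classifier in this package trains several small neural blocks
(a transformer encoder, multi-head self-attention, multi-width text
convolutions, a hypergraph attention network and a fully connected fusion
head) end to end on CPU.  This module provides the minimal tape-based
autodiff needed for that: a :class:`Tensor` wrapping a float64 ndarray, a
set of differentiable primitives, and segment operations (gather /
scatter-sum / per-group softmax) used by the sparse hypergraph layers.

All arrays are float64; gradients are accumulated densely.  The surface is
deliberately small and only covers what the model modules use.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "embedding",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape.

    Parameters created with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # list of (parent Tensor, fn: grad_out -> grad_parent)
        self._parents: list[tuple["Tensor", object]] = []

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents) -> "Tensor":
        out = Tensor(data)
        live = [(p, fn) for p, fn in parents if p.requires_grad]
        if live:
            out.requires_grad = True
            out._parents = live
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward ------------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                pg = fn(g)
                prev = grads.get(id(parent))
                # never accumulate in place: identity backward paths may
                # alias one grad buffer to several nodes
                grads[id(parent)] = pg if prev is None else prev + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        return Tensor._make(
            self.data + other.data,
            [
                (self, lambda g, s=self.data.shape: _unbroadcast(g, s)),
                (other, lambda g, s=other.data.shape: _unbroadcast(g, s)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return Tensor._make(
            self.data * other.data,
            [
                (self, lambda g, o=other.data, s=self.data.shape: _unbroadcast(g * o, s)),
                (other, lambda g, o=self.data, s=other.data.shape: _unbroadcast(g * o, s)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return Tensor._make(
            self.data / other.data,
            [
                (self, lambda g, o=other.data, s=self.data.shape: _unbroadcast(g / o, s)),
                (
                    other,
                    lambda g, a=self.data, o=other.data, s=other.data.shape: _unbroadcast(
                        -g * a / (o * o), s
                    ),
                ),
            ],
        )

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** exponent
        return Tensor._make(
            out,
            [(self, lambda g, x=self.data, e=exponent: g * e * x ** (e - 1))],
        )

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def ga(g):
            return _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)

        def gb(g):
            return _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)

        return Tensor._make(a @ b, [(self, ga), (other, gb)])

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g, o=out: g * o)])

    def log(self):
        return Tensor._make(
            np.log(self.data), [(self, lambda g, x=self.data: g / x)]
        )

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g, o=out: g / (2.0 * o))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, [(self, lambda g, o=out: g * o * (1.0 - o))])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g, o=out: g * (1.0 - o * o))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), [(self, lambda g, m=mask: g * m)]
        )

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = np.where(mask, self.data, slope * self.data)
        return Tensor._make(
            out, [(self, lambda g, m=mask, s=slope: g * np.where(m, 1.0, s))]
        )

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(mask, self.data, expm)
        grad_neg = expm + alpha  # alpha * exp(x) for x <= 0
        return Tensor._make(
            out, [(self, lambda g, m=mask, gn=grad_neg: g * np.where(m, 1.0, gn))]
        )

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), [(self, lambda g, m=mask: g * m)]
        )

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def gfn(g, axis=axis, keepdims=keepdims, shape=self.data.shape):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor._make(out, [(self, gfn)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def gfn(g, axis=axis, keepdims=keepdims):
            ge = g if keepdims else np.expand_dims(g, axis)
            oe = out if keepdims else np.expand_dims(out, axis)
            mask = self.data == oe
            counts = mask.sum(axis=axis, keepdims=True)
            return ge * mask / counts

        return Tensor._make(out, [(self, gfn)])

    # -- shape ops --------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), [(self, lambda g, s=old: g.reshape(s))]
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), [(self, lambda g, i=inv: g.transpose(i))]
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), [(self, lambda g: np.swapaxes(g, a, b))]
        )

    def __getitem__(self, idx):
        out = self.data[idx]

        def gfn(g, idx=idx, shape=self.data.shape):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, idx, g)  # accumulates over repeated fancy indices
            return full

        return Tensor._make(out, [(self, gfn)])

    # -- softmax -----------------------------------------------------------------

    def softmax(self):
        """Softmax along the last axis."""
        x = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(x)
        p = e / e.sum(axis=-1, keepdims=True)

        def gfn(g, p=p):
            dot = (g * p).sum(axis=-1, keepdims=True)
            return p * (g - dot)

        return Tensor._make(p, [(self, gfn)])

    def masked_fill(self, mask: np.ndarray, value: float):
        """Replace entries where ``mask`` is True by ``value`` (no gradient there)."""
        out = np.where(mask, value, self.data)
        return Tensor._make(out, [(self, lambda g, m=mask: np.where(m, 0.0, g))])


# -- free functions ---------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    ax = axis if axis >= 0 else data.ndim + axis
    for t in tensors:
        size = t.data.shape[ax]

        def gfn(g, start=offset, size=size, ax=ax):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(start, start + size)
            return g[tuple(sl)]

        parents.append((t, gfn))
        offset += size
    return Tensor._make(data, parents)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)
    out = weight.data[ids]

    def gfn(g, ids=ids, shape=weight.data.shape):
        full = np.zeros(shape, dtype=np.float64)
        np.add.at(full, ids, g)
        return full

    return Tensor._make(out, [(weight, gfn)])


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """``x[:, idx]`` for x of shape (B, n, ...) and integer index array ``idx``.

    Used to materialize sliding convolution windows.
    """
    idx = np.asarray(idx)
    out = x.data[:, idx]

    def gfn(g, idx=idx, shape=x.data.shape):
        full = np.zeros(shape, dtype=np.float64)
        np.add.at(full, (slice(None), idx), g)
        return full

    return Tensor._make(out, [(x, gfn)])


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` (first axis) into ``n_segments`` groups given by ``seg``."""
    seg = np.asarray(seg)
    out = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out, seg, x.data)
    return Tensor._make(out, [(x, lambda g, seg=seg: g[seg])])


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within groups given by ``seg``.

    Each group's entries are normalized to sum to one; numerically stabilized
    by the per-group maximum.
    """
    seg = np.asarray(seg)
    x = scores.data
    if x.ndim != 1:
        raise ValueError("segment_softmax expects a 1-D score vector")
    gmax = np.full(n_segments, -np.inf)
    np.maximum.at(gmax, seg, x)
    e = np.exp(x - gmax[seg])
    denom = np.zeros(n_segments)
    np.add.at(denom, seg, e)
    p = e / denom[seg]

    def gfn(g, p=p, seg=seg, n=n_segments):
        dot = np.zeros(n)
        np.add.at(dot, seg, p * g)
        return p * (g - dot[seg])

    return Tensor._make(p, [(scores, gfn)])


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when ``training`` is False or ``p == 0``."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
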