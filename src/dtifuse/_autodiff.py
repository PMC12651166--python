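"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The interaction model in this package is a bespoke architecture (graph
convolutions, coordinate attention, grouped multi-scale fusion, cross-
attention) trained end to end.  This module supplies the small tensor/graph
engine it runs on: a :class:`Tensor` wrapper around an ``ndarray``, a set of
differentiable primitives, and an Adam optimiser.  Gradients of every
primitive are verified against central finite differences in the test suite.

Only what the model needs is implemented: broadcasting elementwise
arithmetic, (batched) matmul, reductions, shape ops, a grouped 2-D
convolution (stride 1), an embedding gather and inverted dropout.
"""

from __future__ import annotations

import numpy as np

#: default floating dtype for newly created tensors.  Training runs in
#: float32; gradient-check tests switch to float64 for tight tolerances.
DTYPE = np.float32

_FLOAT_TYPES = (np.float32, np.float64)


def _cast(data):
    arr = np.asarray(data)
    if arr.dtype in _FLOAT_TYPES:
        return arr
    return arr.astype(DTYPE)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _cast(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, seed=None):
        """Backpropagate from this tensor.

        ``seed`` defaults to ones (appropriate for scalar losses).
        """
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if seed is None else _cast(seed))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other, like=self), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other, like=self), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.dtype not in _FLOAT_TYPES:
        arr = arr.astype(like.data.dtype if like is not None else DTYPE)
    return Tensor(arr)


def _node(data, parents, backward) -> Tensor:
    """Create a graph node; drops the closure if no parent needs grads."""
    out = Tensor(data)
    parents = tuple(parents)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b, like=a)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a, b):
    a = as_tensor(a)
    b = as_tensor(b, like=a)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a, b):
    a = as_tensor(a)
    b = as_tensor(b, like=a)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(a.data / b.data, (a, b), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    # numerically stable logistic
    y = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                 np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    y = y.astype(a.data.dtype)

    def backward(g):
        if a.requires_grad:
            a._accum(g * y * (1.0 - y))

    return _node(y, (a,), backward)


def exp(a):
    a = as_tensor(a)
    y = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * y)

    return _node(y, (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def sqrt(a):
    a = as_tensor(a)
    y = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * 0.5 / y)

    return _node(y, (a,), backward)


def clip(a, lo, hi):
    """Clamp values; gradient passes only through the un-clipped region."""
    a = as_tensor(a)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        if a.requires_grad:
            a._accum(g * inside)

    return _node(np.clip(a.data, lo, hi), (a,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    axes = _norm_axes(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                for ax in sorted(axes):
                    g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    axes = _norm_axes(axis, a.ndim)
    n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axes, keepdims=keepdims), 1.0 / n)


def tmax(a, axis, keepdims=False):
    """Max along a single axis; gradient flows to the first argmax."""
    a = as_tensor(a)
    axis = axis % a.ndim
    idx = np.expand_dims(np.argmax(a.data, axis=axis), axis)
    out_data = np.take_along_axis(a.data, idx, axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if a.requires_grad:
            gk = g if keepdims else np.expand_dims(g, axis)
            ga = np.zeros_like(a.data)
            np.put_along_axis(ga, idx, gk, axis=axis)
            a._accum(ga)

    return _node(out_data, (a,), backward)


def softmax(a, axis=-1):
    """Softmax along ``axis`` (composite; max-shift is constant)."""
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)
    e = exp(add(a, Tensor(-shift)))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    old = a.shape

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def slice_axis(a, axis, start, stop):
    a = as_tensor(a)
    axis = axis % a.ndim
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[sl] = g
            a._accum(ga)

    return _node(a.data[sl], (a,), backward)


# ---------------------------------------------------------------------------
# embedding lookup
# ---------------------------------------------------------------------------

def embedding(table, indices):
    """Row gather ``table[indices]``; backward scatter-adds."""
    table = as_tensor(table)
    idx = np.asarray(indices)

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.reshape(-1),
                      g.reshape(-1, table.shape[-1]))
            table._accum(gt)

    return _node(table.data[idx], (table,), backward)


# ---------------------------------------------------------------------------
# grouped 2-D convolution, stride 1
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, groups: int = 1, padding=(0, 0)):
    """Grouped stride-1 2-D convolution (cross-correlation).

    x: (B, C, H, W); w: (Cout, C/groups, kh, kw); b: (Cout,) or None.
    ``padding`` is a (ph, pw) pair of symmetric zero pads.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    b = as_tensor(b) if b is not None else None
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    ph, pw = padding
    if C % groups or Cout % groups or C // groups != Cg:
        raise ValueError(
            f"conv2d channel mismatch: C={C}, Cout={Cout}, groups={groups}, "
            f"kernel expects {Cg} input channels per group")
    if kh > H + 2 * ph or kw > W + 2 * pw:
        raise ValueError(
            f"conv2d kernel ({kh}x{kw}) larger than padded spatial extent "
            f"({H + 2 * ph}x{W + 2 * pw})")
    Og = Cout // groups

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    Ho, Wo = win.shape[2], win.shape[3]
    wing = win.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, Og, Cg, kh, kw)
    out = np.einsum("bgchwij,gocij->bgohw", wing, wg, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        go = g.reshape(B, groups, Og, Ho, Wo)
        if w.requires_grad:
            gw = np.einsum("bgchwij,bgohw->gocij", wing, go, optimize=True)
            w._accum(gw.reshape(Cout, Cg, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of the output grad with the flipped kernel
            gp = np.pad(g, ((0, 0), (0, 0),
                            (kh - 1 - ph, kh - 1 - ph),
                            (kw - 1 - pw, kw - 1 - pw)))
            gwin = np.lib.stride_tricks.sliding_window_view(
                gp, (kh, kw), axis=(2, 3))
            gwin = gwin.reshape(B, groups, Og, H, W, kh, kw)
            wf = wg[:, :, :, ::-1, ::-1]
            gx = np.einsum("bgohwij,gocij->bgchw", gwin, wf, optimize=True)
            x._accum(gx.reshape(B, C, H, W))

    return _node(out, (x, w) + ((b,) if b is not None else ()), backward)


def conv1d(x, w, b=None, padding: int = 0):
    """Stride-1 1-D convolution over (B, C, L) via the 2-D kernel."""
    x = as_tensor(x)
    w = as_tensor(w)
    B, C, L = x.shape
    Cout, Cin, k = w.shape
    x4 = reshape(x, (B, C, 1, L))
    w4 = reshape(w, (Cout, Cin, 1, k))
    out = conv2d(x4, w4, b=b, padding=(0, padding))
    return reshape(out, (B, Cout, out.shape[-1]))


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------

def dropout(a, rate: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity when not training or rate == 0."""
    a = as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = (rng.random(a.shape) >= rate).astype(a.data.dtype) / (1.0 - rate)

    def backward(g):
        if a.requires_grad:
            a._accum(g * keep)

    return _node(a.data * keep, (a,), backward)


# ---------------------------------------------------------------------------
# parameters and optimisation
# ---------------------------------------------------------------------------

def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
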