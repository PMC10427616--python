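"""Minimal reverse-mode automatic differentiation over numpy arrays.

The pair-representation network needs a handful of differentiable
primitives (dense maps, 2-D convolution, softmax attention, einsum-style
contractions, normalisation).  This module provides exactly those as a
tape-based autodiff: every operation records its parents and a closure
that maps the upstream gradient to contributions for each parent.

Only what the contact network uses is implemented; each primitive is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant", "no_grad",
    "add", "sub", "mul", "div", "neg", "pow_const",
    "exp", "log", "sqrt", "sigmoid", "elu", "clip",
    "matmul", "einsum", "conv2d",
    "softmax", "reduce_sum", "reduce_mean", "transpose2d", "reshape",
    "concat", "dropout_mask",
]


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager: ops inside build no tape (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entries needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_name")

    def __init__(self, data, requires_grad: bool = False, parents=(), name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        if _GRAD_ENABLED[0]:
            self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)
        else:
            self.requires_grad = False
        # parents: sequence of (Tensor, fn(upstream_grad) -> grad_contribution)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self._name!r})"

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = g.copy() if t._parents == () else g
            else:
                t.grad = t.grad + g
            for p, fn in t._parents:
                if not p.requires_grad:
                    continue
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib

    def zero_grad(self):
        self.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _coerce(a, b):
    """Wrap operands; python scalars adopt the other operand's dtype."""
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return constant(a), constant(b)


# -- elementwise ---------------------------------------------------------

def add(a, b):
    a, b = _coerce(a, b)
    return Tensor(a.data + b.data, parents=(
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ))


def sub(a, b):
    a, b = _coerce(a, b)
    return Tensor(a.data - b.data, parents=(
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(-g, b.data.shape)),
    ))


def neg(a):
    a = constant(a)
    return Tensor(-a.data, parents=((a, lambda g: -g),))


def mul(a, b):
    a, b = _coerce(a, b)
    return Tensor(a.data * b.data, parents=(
        (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
    ))


def div(a, b):
    a, b = _coerce(a, b)
    return Tensor(a.data / b.data, parents=(
        (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
    ))


def pow_const(a, p: float):
    a = constant(a)
    return Tensor(a.data ** p, parents=((a, lambda g: g * p * a.data ** (p - 1)),))


def exp(a):
    a = constant(a)
    out = np.exp(a.data)
    return Tensor(out, parents=((a, lambda g: g * out),))


def log(a):
    a = constant(a)
    return Tensor(np.log(a.data), parents=((a, lambda g: g / a.data),))


def sqrt(a):
    a = constant(a)
    out = np.sqrt(a.data)
    return Tensor(out, parents=((a, lambda g: g * 0.5 / out),))


def sigmoid(a):
    a = constant(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(out, parents=((a, lambda g: g * out * (1.0 - out)),))


def elu(a, alpha: float = 1.0):
    a = constant(a)
    neg_part = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out = np.where(a.data > 0, a.data, neg_part)
    dneg = neg_part + alpha  # alpha * exp(x) on the negative branch
    return Tensor(out, parents=((a, lambda g: g * np.where(a.data > 0, 1.0, dneg)),))


def clip(a, lo: float, hi: float):
    """Clamp values; gradient is passed through only inside the interval."""
    a = constant(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)
    return Tensor(out, parents=((a, lambda g: g * inside),))


# -- linear algebra ------------------------------------------------------

def matmul(a, b):
    a, b = constant(a), constant(b)
    out = a.data @ b.data

    def da(g):
        grad = g @ np.swapaxes(b.data, -1, -2)
        return _unbroadcast(grad, a.data.shape)

    def db(g):
        grad = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(grad, b.data.shape)

    return Tensor(out, parents=((a, da), (b, db)))


def einsum(equation: str, a, b):
    """Two-operand einsum.

    Restriction: no index may repeat within a single operand subscript
    (no internal traces/diagonals), which makes the adjoint another
    einsum with permuted subscripts.
    """
    a, b = constant(a), constant(b)
    lhs, out_sub = equation.split("->")
    sa, sb = lhs.split(",")
    for s in (sa, sb, out_sub):
        if len(set(s)) != len(s):
            raise ValueError(f"repeated index within one subscript: {equation}")
    out = np.einsum(equation, a.data, b.data, optimize=True)

    def da(g):
        return np.einsum(f"{out_sub},{sb}->{sa}", g, b.data, optimize=True)

    def db(g):
        return np.einsum(f"{sa},{out_sub}->{sb}", a.data, g, optimize=True)

    return Tensor(out, parents=((a, da), (b, db)))


def conv2d(x, w, b=None):
    """Same-padding 2-D convolution, channels-last, single sample.

    x: (H, W, Cin); w: (k, k, Cin, Cout); b: (Cout,) or None.
    """
    x, w = constant(x), constant(w)
    k = w.data.shape[0]
    assert w.data.shape[1] == k and k % 2 == 1
    H, W, cin = x.data.shape
    cout = w.data.shape[3]
    if k == 1:  # pointwise: plain matmul, no patch extraction
        wm1 = w.data.reshape(cin, cout)
        out = x.data.reshape(H * W, cin) @ wm1
        if b is not None:
            b = constant(b)
            out = out + b.data
        parents = [
            (x, lambda g: (g.reshape(H * W, cout) @ wm1.T).reshape(H, W, cin)),
            (w, lambda g: (x.data.reshape(H * W, cin).T
                           @ g.reshape(H * W, cout)).reshape(w.data.shape)),
        ]
        if b is not None:
            parents.append((b, lambda g: g.reshape(H * W, cout).sum(axis=0)))
        return Tensor(out.reshape(H, W, cout), parents=tuple(parents))
    pad = k // 2
    xp = np.pad(x.data, ((pad, pad), (pad, pad), (0, 0)))
    # patches: (H, W, k, k, Cin)
    patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
    patches = np.moveaxis(patches, (3, 4), (2, 3))
    cols = patches.reshape(H * W, k * k * cin)
    wm = w.data.reshape(k * k * cin, cout)
    out = cols @ wm
    if b is not None:
        b = constant(b)
        out = out + b.data
    out = out.reshape(H, W, cout)

    def dx(g):
        gm = g.reshape(H * W, cout)
        dcols = (gm @ wm.T).reshape(H, W, k, k, cin)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                dxp[di:di + H, dj:dj + W, :] += dcols[:, :, di, dj, :]
        return dxp[pad:pad + H, pad:pad + W, :]

    def dw(g):
        gm = g.reshape(H * W, cout)
        return (cols.T @ gm).reshape(w.data.shape)

    parents = [(x, dx), (w, dw)]
    if b is not None:
        parents.append((b, lambda g: g.reshape(H * W, cout).sum(axis=0)))
    return Tensor(out.copy(), parents=tuple(parents))


# -- reductions / shaping -----------------------------------------------

def reduce_sum(a, axis=None, keepdims=False):
    a = constant(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def da(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis=axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return Tensor(out, parents=((a, da),))


def reduce_mean(a, axis=None, keepdims=False):
    a = constant(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[i] for i in axis]))
    else:
        n = a.data.shape[axis]
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def transpose2d(a):
    """Swap the first two axes (pair-map transpose)."""
    a = constant(a)
    axes = (1, 0) + tuple(range(2, a.data.ndim))
    return Tensor(np.transpose(a.data, axes), parents=((a, lambda g: np.transpose(g, axes)),))


def reshape(a, shape):
    a = constant(a)
    old = a.data.shape
    return Tensor(a.data.reshape(shape), parents=((a, lambda g: g.reshape(old)),))


def concat(tensors, axis=-1):
    tensors = [constant(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    ax = axis if axis >= 0 else out.ndim + axis

    def make_fn(i):
        sl = [slice(None)] * out.ndim
        sl[ax] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=tuple((t, make_fn(i)) for i, t in enumerate(tensors)))


def softmax(a, axis: int = -1, mask: np.ndarray | None = None):
    """Numerically stable softmax with optional boolean key mask.

    mask (broadcastable to a.shape): True = position participates.  If
    every position along `axis` is masked out for some slice, that
    slice's output is all zeros (and passes zero gradient), matching the
    "all keys masked -> attention contributes nothing" contract.
    """
    a = constant(a)
    x = a.data
    if mask is not None and bool(np.all(mask)):
        mask = None
    if mask is None:
        m = np.max(x, axis=axis, keepdims=True)
        e = np.exp(x - m)
        out = e / e.sum(axis=axis, keepdims=True)
    else:
        x = np.where(mask, x, -np.inf)
        m = np.max(x, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)  # all-masked slices
        e = np.exp(x - m)
        denom = e.sum(axis=axis, keepdims=True)
        out = np.where(denom > 0, e / np.where(denom > 0, denom, 1.0), 0.0)

    def da(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return Tensor(out, parents=((a, da),))


def affine_norm(x, gamma, beta, axes, eps: float = 1e-5):
    """Fused normalisation over `axes` with affine scale/shift.

    Layer norm (axes=-1) and instance norm (axes=(0, 1)) share this
    kernel; fusing it keeps the tape short on the hot path.
    """
    x, gamma, beta = constant(x), constant(gamma), constant(beta)
    axes = (axes,) if isinstance(axes, int) else tuple(axes)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.data.dtype))
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def dx(g):
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)

    def dgamma(g):
        return _unbroadcast(g * xhat, gamma.data.shape)

    def dbeta(g):
        return _unbroadcast(g, beta.data.shape)

    return Tensor(out, parents=((x, dx), (gamma, dgamma), (beta, dbeta)))


def dropout_mask(a, p: float, rng: np.random.Generator):
    """Inverted dropout: scales kept activations by 1/(1-p)."""
    a = constant(a)
    if p <= 0.0:
        return a
    keep = ((rng.random(a.data.shape) >= p) / (1.0 - p)).astype(a.data.dtype)
    return Tensor(a.data * keep, parents=((a, lambda g: g * keep),))
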