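"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine provides exactly the operator set the phosphene-encoding
pipeline needs: 3x3 convolutions, 2x2 max pooling, batch normalization,
leaky rectifiers, sigmoids, linear layers, a straight-through Heaviside
for binary electrode activation, a clipped linear phosphene-rendering
operator, and the two losses (feature-matching MSE and cross-entropy).

Design: define-by-run tape.  Each :class:`Tensor` remembers its parents
and a closure that propagates the output gradient to them.  ``backward``
walks the graph in reverse topological order.  Arrays are float32 by
default (float64 is available for finite-difference gradient checks via
:func:`set_default_dtype`).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    """Set the dtype used for new tensors (float32 or float64)."""
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("only float32/float64 supported")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(p for p in parents if p.requires_grad) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if not self.requires_grad:
            raise RuntimeError("tensor does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad only valid for scalars")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self):
        return tsum(self)

    def mean(self):
        return tmean(self)

    def reshape(self, *shape):
        return reshape(self, shape)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents, backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    if a.data.shape != b.data.shape:
        raise ValueError("add requires identical shapes (no implicit broadcast)")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError("sub requires identical shapes")
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    return _make(out_data, (a, b), backward)


def mul(a, scalar) -> Tensor:
    """Multiply a tensor by a python scalar."""
    a = as_tensor(a)
    s = float(scalar)
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _make(out_data, (a,), backward)


def square(a) -> Tensor:
    a = as_tensor(a)
    out_data = a.data * a.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(2.0 * a.data * g)

    return _make(out_data, (a,), backward)


def tsum(a) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum()

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size
    out_data = a.data.mean()

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape))

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def concat_channels(a, n: int) -> Tensor:
    """Replicate a single-channel NCHW tensor to ``n`` channels."""
    a = as_tensor(a)
    if a.ndim != 4 or a.shape[1] != 1:
        raise ValueError("concat_channels expects (N,1,H,W)")
    out_data = np.repeat(a.data, n, axis=1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.sum(axis=1, keepdims=True))

    return _make(out_data, (a,), backward)


def affine_const(a, scale: float, shift: float) -> Tensor:
    """Elementwise ``a * scale + shift`` with constant scalars."""
    a = as_tensor(a)
    out_data = a.data * scale + shift

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * scale)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.where(pos, g, slope * g))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def heaviside_st(a, threshold: float = 0.5) -> Tensor:
    """Binarize at ``threshold`` (strict >) with a straight-through backward.

    Forward emits hard 0/1 values; the backward pass treats the step as the
    identity on its input, so gradients reach the pre-threshold activations
    unchanged.  This keeps a binary electrode map trainable end to end.
    """
    a = as_tensor(a)
    out_data = (a.data > threshold).astype(a.data.dtype)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)

    return _make(out_data, (a,), backward)


def clip01(a) -> Tensor:
    """Clip to [0,1]; gradient passes only through the interior."""
    a = as_tensor(a)
    out_data = np.clip(a.data, 0.0, 1.0)
    interior = (a.data > 0.0) & (a.data < 1.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.where(interior, g, 0.0))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# linear algebra layers
# ---------------------------------------------------------------------------

def linear(x, w, b) -> Tensor:
    """``x @ w.T + b`` for x:(N,F), w:(O,F), b:(O,)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    out_data = x.data @ w.data.T + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    return _make(out_data, (x, w, b), backward)


def conv2d_3x3(x, w, b) -> Tensor:
    """3x3 convolution, stride 1, zero padding 1.

    x: (N,C,H,W); w: (O,C,3,3); b: (O,).  Implemented as nine shifted
    tensordots so each offset is one BLAS matmul; the backward reuses the
    padded input.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    if w.data.shape != (o, c, 3, 3):
        raise ValueError(f"weight shape {w.data.shape} incompatible with input channels {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    acc = np.zeros((n, h, wd, o), dtype=x.data.dtype)
    for i in range(3):
        for j in range(3):
            acc += np.tensordot(xp[:, :, i:i + h, j:j + wd], w.data[:, :, i, j],
                                axes=([1], [1]))
    acc += b.data
    out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,H,W,O)
        if w.requires_grad or b.requires_grad:
            if b.requires_grad:
                b._accumulate(gt.sum(axis=(0, 1, 2)))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(3):
                    for j in range(3):
                        gw[:, :, i, j] = np.tensordot(
                            gt, xp[:, :, i:i + h, j:j + wd],
                            axes=([0, 1, 2], [0, 2, 3]))
                w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    gxp[:, :, i:i + h, j:j + wd] += np.tensordot(
                        gt, w.data[:, :, i, j], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
            x._accumulate(gxp[:, :, 1:1 + h, 1:1 + wd])

    return _make(out_data, (x, w, b), backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling, stride 2.  H and W must be even."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))

    return _make(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _make(out_data, (x,), backward)


def batchnorm2d(x, gamma, beta, running_mean, running_var, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel.

    ``running_mean``/``running_var`` are plain numpy arrays mutated in place
    during training (standard running-statistics behavior).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance for the running estimate
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mean = running_mean.astype(x.data.dtype)
        var = running_var.astype(x.data.dtype)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                m = n * h * w
                sum_gs = gs.sum(axis=(0, 2, 3))
                sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3))
                gx = (inv_std[None, :, None, None] / m) * (
                    m * gs
                    - sum_gs[None, :, None, None]
                    - xhat * sum_gs_xhat[None, :, None, None]
                )
            else:
                gx = gs * inv_std[None, :, None, None]
            x._accumulate(gx)

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy_logits(logits, labels) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    out_data = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * p / n)

    return _make(out_data, (logits,), backward)


def feature_mse(a, b) -> Tensor:
    """Mean squared elementwise difference (squared L2 / element count)."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    n = diff.size
    out_data = np.asarray((diff ** 2).sum() / n, dtype=a.data.dtype)

    def backward(g):
        scaled = (2.0 / n) * diff * g
        if a.requires_grad:
            a._accumulate(scaled)
        if b.requires_grad:
            b._accumulate(-scaled)

    return _make(out_data, (a, b), backward)


def phosphene_render(m, template: np.ndarray, brightness: float = 1.0) -> Tensor:
    """Linear dot rendering: Kronecker expansion of a grid map by a template.

    m: (N,G,G) activation values; template: (s,s) dot profile confined to one
    grid cell.  Output: (N,G*s,G*s), clipped to [0,1].  The operator is linear
    before clipping, so it composes with gradient-based training.
    """
    m = as_tensor(m)
    n, g1, g2 = m.data.shape
    s = template.shape[0]
    tmpl = template.astype(m.data.dtype)
    raw = (m.data[:, :, None, :, None] * tmpl[None, :, None, :] * brightness)
    raw = raw.reshape(n, g1 * s, g2 * s)
    out_data = np.clip(raw, 0.0, 1.0)
    # clip gradient passes where raw lies in [0,1]; boundary included so the
    # operator stays exactly linear for frames that never saturate
    mask = (raw >= 0.0) & (raw <= 1.0)

    def backward(g):
        if m.requires_grad:
            gr = (g * mask).reshape(n, g1, s, g2, s) * brightness
            gm = np.einsum("ngsht,st->ngh", gr, tmpl)
            m._accumulate(gm)

    return _make(out_data, (m,), backward)
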