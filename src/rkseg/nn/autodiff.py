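"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the segmentation networks need:
same-padded 3x3 and 1x1 convolution, per-channel instance normalization,
leaky ReLU, 2x2 max pooling, matrix-based bilinear/nearest up-sampling,
channel concatenation and elementwise addition.  Each operation records a
closure that propagates the output gradient to its inputs; ``backward()``
runs them in reverse topological order.

Convolution gradients reuse convolution itself: the input gradient of a
same-padded 3x3 correlation is the correlation of the output gradient with
the spatially flipped, channel-transposed kernel, and the weight gradient
is an im2col contraction.  Gradients of every primitive are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An n-d array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag}, name={self.name!r})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs are deep for large depths)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _needs_graph(*tensors: Tensor) -> bool:
    if not _grad_enabled:
        return False
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward_factory):
    """Create an op output; record the backward closure only when needed."""
    if _needs_graph(*parents):
        return Tensor(data, parents=parents, backward=backward_factory())
    return Tensor(data)


# ---------------------------------------------------------------- conv ----

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*9) patch matrix for same-padded 3x3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * 9)


def _conv3_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 3x3 correlation, no bias."""
    n, c, h, wd = x.shape
    k = w.shape[0]
    col = _im2col3(x)                         # (N, HW, C*9)
    out = col @ w.reshape(k, c * 9).T         # (N, HW, K)
    return out.transpose(0, 2, 1).reshape(n, k, h, wd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2-D correlation; kernel 3x3 (same padding) or 1x1, stride 1."""
    w = weight.data
    kh, kw = w.shape[2], w.shape[3]
    if x.data.shape[1] != w.shape[1]:
        raise ValueError(f"channel mismatch: input {x.data.shape[1]}, kernel {w.shape[1]}")
    if (kh, kw) == (3, 3):
        out = _conv3_raw(x.data, w)
    elif (kh, kw) == (1, 1):
        out = np.einsum("nchw,kc->nkhw", x.data, w[:, :, 0, 0], optimize=True)
    else:
        raise ValueError(f"unsupported kernel size {(kh, kw)}")
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def factory():
        def backward(g):
            n, k = g.shape[0], g.shape[1]
            if (kh, kw) == (3, 3):
                if x.requires_grad or x._parents:
                    w_flip = np.ascontiguousarray(
                        w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                    )
                    x._accumulate(_conv3_raw(g, w_flip))
                if weight.requires_grad or weight._parents:
                    col = _im2col3(x.data)                       # (N,HW,C*9)
                    gf = g.reshape(n, k, -1)                     # (N,K,HW)
                    dw = np.einsum("nkp,npc->kc", gf, col, optimize=True)
                    weight._accumulate(dw.reshape(w.shape))
            else:
                if x.requires_grad or x._parents:
                    x._accumulate(
                        np.einsum("nkhw,kc->nchw", g, w[:, :, 0, 0], optimize=True)
                    )
                if weight.requires_grad or weight._parents:
                    dw = np.einsum("nkhw,nchw->kc", g, x.data, optimize=True)
                    weight._accumulate(dw.reshape(w.shape))
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        return backward

    return _make(out, parents, factory)


# ------------------------------------------------------- normalization ----

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization with learnable affine."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def factory():
        def backward(g):
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad or beta._parents:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                dxhat = g * gamma.data.reshape(1, -1, 1, 1)
                m1 = dxhat.mean(axis=(2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
                x._accumulate(inv_std * (dxhat - m1 - xhat * m2))

        return backward

    return _make(out, (x, gamma, beta), factory)


# -------------------------------------------------------- nonlinearity ----

def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def factory():
        def backward(g):
            x._accumulate(np.where(mask, g, slope * g))

        return backward

    return _make(out, (x,), factory)


# -------------------------------------------------------------- pooling ----

def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial size, got {(h, w)}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def factory():
        def backward(g):
            dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(n, c, h, w))

        return backward

    return _make(out, (x,), factory)


# ------------------------------------------------------------ resampling ----

@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """1-D up-sampling matrix (n_out x n_in), align_corners=False convention."""
    m = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        if mode == "nearest":
            m[o, min(n_in - 1, max(0, int(np.floor((o + 0.5) * scale))))] = 1.0
            continue
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        m[o, i0] += 1.0 - frac
        m[o, i1] += frac
    return m


def upsample(x: Tensor, factor: int, mode: str = "bilinear") -> Tensor:
    """Up-sample by an integer factor along both spatial axes."""
    if factor == 1:
        return x
    n, c, h, w = x.data.shape
    mr = _interp_matrix(h, h * factor, mode).astype(x.data.dtype)
    mc = _interp_matrix(w, w * factor, mode).astype(x.data.dtype)
    tmp = np.einsum("Hh,nchw->ncHw", mr, x.data, optimize=True)
    out = np.einsum("Ww,ncHw->ncHW", mc, tmp, optimize=True)

    def factory():
        def backward(g):
            t = np.einsum("Ww,ncHW->ncHw", mc, g, optimize=True)
            x._accumulate(np.einsum("Hh,ncHw->nchw", mr, t, optimize=True))

        return backward

    return _make(out, (x,), factory)


# ----------------------------------------------------------- structural ----

def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    if len(tensors) == 1:
        return tensors[0]
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def factory():
        def backward(g):
            start = 0
            for t, sz in zip(tensors, sizes):
                if t.requires_grad or t._parents:
                    t._accumulate(g[:, start:start + sz])
                start += sz

        return backward

    return _make(out, tuple(tensors), factory)


def add(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError(f"shape mismatch in add: {x.data.shape} vs {y.data.shape}")
    out = x.data + y.data

    def factory():
        def backward(g):
            if x.requires_grad or x._parents:
                x._accumulate(g)
            if y.requires_grad or y._parents:
                y._accumulate(g)

        return backward

    return _make(out, (x, y), factory)


def add_n(tensors: list[Tensor]) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = add(out, t)
    return out
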