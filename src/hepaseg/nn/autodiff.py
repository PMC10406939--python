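"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` runs the chain rule over the recorded
graph in reverse topological order.  Only the operations the segmentation
network needs are provided (elementwise arithmetic with broadcasting,
matmul, stride-1 cross-correlation, 2x2 max pooling, bilinear 2x
upsampling, batch normalization, ReLU/sigmoid/log, pooling and
concatenation).  Everything is single-threaded numpy, so results are
bit-reproducible run to run.

Gradient formulas are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "matmul",
    "conv2d",
    "relu",
    "sigmoid",
    "log",
    "maxpool2x2",
    "upsample_bilinear2x",
    "batch_norm2d",
    "global_avg_pool",
    "concat",
    "tsum",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free closures so activation caches can be collected
        for node in topo:
            node._backward = None
            node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _add_back)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return _binary(self, other, np.divide, _div_back)

    def __rtruediv__(self, other):
        return _binary(_as_tensor(other), self, np.divide, _div_back)

    def reshape(self, *shape):
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            orig = self.data.shape

            def back(g, self=self, orig=orig):
                _accum(self, g.reshape(orig))

            out._backward = back
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _needs_graph(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = parents
        out.requires_grad = True
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _add_back(a, b, out_g, _data):
    _accum(a, _unbroadcast(out_g, a.data.shape))
    _accum(b, _unbroadcast(out_g, b.data.shape))


def _mul_back(a, b, out_g, _data):
    _accum(a, _unbroadcast(out_g * b.data, a.data.shape))
    _accum(b, _unbroadcast(out_g * a.data, b.data.shape))


def _div_back(a, b, out_g, out_data):
    _accum(a, _unbroadcast(out_g / b.data, a.data.shape))
    _accum(b, _unbroadcast(-out_g * out_data / b.data, b.data.shape))


def _binary(a, b, fwd, back) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:
        out_data = out.data

        def _bw(g, a=a, b=b, out_data=out_data):
            back(a, b, g, out_data)

        out._backward = _bw
    return out


# -- dense / conv ---------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product a @ b."""
    out = _make(a.data @ b.data, (a, b))
    if out._parents:

        def back(g, a=a, b=b):
            _accum(a, g @ b.data.T)
            _accum(b, a.data.T @ g)

        out._backward = back
    return out


def _corr_raw(x: np.ndarray, w: np.ndarray, padding: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 cross-correlation; returns (output NCHW, im2col matrix).

    1x1 kernels bypass im2col entirely (pure channel contraction); the
    returned im2col matrix is then None.
    """
    n, c, h, wd = x.shape
    cout, cin, kh, kw = w.shape
    if kh == 1 and kw == 1 and padding == 0:
        out = np.tensordot(x, w[:, :, 0, 0], axes=([1], [1]))  # n,h,w,cout
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), None
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = x.shape[2] - kh + 1
    wo = x.shape[3] - kw + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # n,c,ho,wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    out = cols @ w.reshape(cout, -1).T
    return out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D cross-correlation (NCHW) with optional per-channel bias."""
    need = _needs_graph(x, w) or (b is not None and _needs_graph(b))
    out_data, cols = _corr_raw(x.data, w.data, padding)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if need and _GRAD_ENABLED:
        out.requires_grad = True
        out._parents = parents
        cout, cin, kh, kw = w.data.shape

        def back(g, x=x, w=w, b=b, cols=cols, padding=padding, kh=kh, kw=kw):
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))
            if cols is None:  # 1x1 fast path
                gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
                _accum(w, gw.reshape(w.data.shape))
                if x.requires_grad or x._parents:
                    gx = np.tensordot(g, w.data[:, :, 0, 0], axes=([1], [0]))
                    _accum(x, np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
                return
            g_cols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, g.shape[1])
            _accum(w, (g_cols.T @ cols).reshape(w.data.shape))
            if x.requires_grad or x._parents:
                # dL/dx = correlation of g with the spatially flipped,
                # channel-transposed kernel, padded by k-1-p
                w_t = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
                gx, _ = _corr_raw(g, np.ascontiguousarray(w_t), kh - 1 - padding)
                _accum(x, gx)

        out._backward = back
    return out


# -- activations ----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._parents:
        mask = x.data > 0

        def back(g, x=x, mask=mask):
            _accum(x, g * mask)

        out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    # clip the logit so float32 exp never overflows; sigmoid saturates far earlier
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = _make(s, (x,))
    if out._parents:

        def back(g, x=x, s=s):
            _accum(x, g * s * (1.0 - s))

        out._backward = back
    return out


def log(x: Tensor) -> Tensor:
    out = _make(np.log(x.data), (x,))
    if out._parents:

        def back(g, x=x):
            _accum(x, g / x.data)

        out._backward = back
    return out


# -- spatial --------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = _make(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], (x,))
    if out._parents:

        def back(g, x=x, idx=idx, n=n, c=c, h=h, w=w):
            gw = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            _accum(x, gx.reshape(n, c, h, w))

        out._backward = back
    return out


_INTERP_CACHE: dict[int, np.ndarray] = {}


def _interp_matrix(n_in: int) -> np.ndarray:
    """1-D bilinear 2x upsampling operator (2n x n), align_corners=False."""
    m = _INTERP_CACHE.get(n_in)
    if m is None:
        n_out = 2 * n_in
        m = np.zeros((n_out, n_in), dtype=np.float32)
        for o in range(n_out):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            m[o, i0c] += 1.0 - frac
            m[o, i1c] += frac
        _INTERP_CACHE[n_in] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (separable, exact linear operator)."""
    n, c, h, w = x.data.shape
    ah, aw = _interp_matrix(h), _interp_matrix(w)
    out_data = ah @ x.data @ aw.T
    out = _make(out_data, (x,))
    if out._parents:

        def back(g, x=x, ah=ah, aw=aw):
            _accum(x, ah.T @ g @ aw)

        out._backward = back
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial dims: (N,C,H,W) -> (N,C)."""
    n, c, h, w = x.data.shape
    out = _make(x.data.mean(axis=(2, 3)), (x,))
    if out._parents:

        def back(g, x=x, h=h, w=w):
            _accum(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

        out._backward = back
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization with running statistics.

    In training mode batch statistics are used and the running buffers
    updated in place; in eval mode the buffers are used and receive no
    gradient contribution.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * ivar[None, :, None, None]
    out = _make(xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None],
                (x, gamma, beta))
    if out._parents:

        def back(g, x=x, gamma=gamma, beta=beta, xhat=xhat, ivar=ivar, training=training):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            if not (x.requires_grad or x._parents):
                return
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - sum_g / m - xhat * sum_gx / m) * ivar[None, :, None, None]
            else:
                gx = gxhat * ivar[None, :, None, None]
            _accum(x, gx.astype(np.float32))

        out._backward = back
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]

        def back(g, tensors=tensors, sizes=sizes, axis=axis):
            splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
            for t, gs in zip(tensors, splits):
                _accum(t, gs)

        out._backward = back
    return out


def tsum(x: Tensor) -> Tensor:
    """Sum of all elements -> scalar tensor."""
    out = _make(np.asarray(x.data.sum()), (x,))
    if out._parents:

        def back(g, x=x):
            _accum(x, np.broadcast_to(g, x.data.shape))

        out._backward = back
    return out
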