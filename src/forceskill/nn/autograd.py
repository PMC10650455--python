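"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape: each :class:`Tensor` remembers its parents and a
closure that routes the output gradient back to them.  Sequence-level
operations that would be slow as per-step primitive graphs (LSTM, GRU,
convolution, pooling, batch normalization, attention softmax) are implemented
as fused ops with hand-derived vector-Jacobian products; every fused backward
is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "matmul", "relu", "sigmoid", "tanh",
    "mean", "sum_", "reshape", "transpose", "concat", "gather_time", "slice_lastdim",
    "softmax", "bce_with_logits", "conv1d", "maxpool1d",
    "batchnorm_train", "batchnorm_eval", "lstm", "gru", "reverse_time",
    "scale", "add_scalar",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar used sparingly in layer code
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self, grad=None):
        """Backpropagate from this node through the whole graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    else:
        out.requires_grad = False
        out._parents = ()
        out._backward = None
    return out


def _accum(t: Tensor, g: np.ndarray):
    g = np.asarray(g, dtype=t.data.dtype)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a, s: float):
    a = _as_tensor(a)
    data = a.data * s

    def backward(g):
        _accum(a, g * s)

    return _make(data, (a,), backward)


def add_scalar(a, s: float):
    a = _as_tensor(a)
    data = a.data + s

    def backward(g):
        _accum(a, g)

    return _make(data, (a,), backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0)

    def backward(g):
        _accum(a, g * mask)

    return _make(data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    data = _sigmoid(a.data)

    def backward(g):
        _accum(a, g * data * (1 - data))

    return _make(data, (a,), backward)


def tanh(a):
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1 - data * data))

    return _make(data, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mean(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape) / n)

    return _make(data, (a,), backward)


def sum_(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(data, (a,), backward)


def reshape(a, shape):
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes):
    a = _as_tensor(a)
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, np.transpose(g, inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int = -1):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def gather_time(a, idx):
    """Select one time step per batch item: (B, T, H), (B,) -> (B, H)."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(a.data.shape[0])
    data = a.data[rows, idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[rows, idx] = g
        _accum(a, ga)

    return _make(data, (a,), backward)


def slice_lastdim(a, lo: int, hi: int):
    a = _as_tensor(a)
    data = a.data[..., lo:hi]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[..., lo:hi] = g
        _accum(a, ga)

    return _make(np.ascontiguousarray(data), (a,), backward)


def softmax(a, axis: int = -1):
    a = _as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    ex = np.exp(x)
    data = ex / ex.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        _accum(a, data * (g - dot))

    return _make(data, (a,), backward)


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    # log(1 + e^-|z|) + max(z, 0) - z*t
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    data = np.asarray(loss.mean(), dtype=logits.data.dtype)
    p = _sigmoid(z)

    def backward(g):
        _accum(logits, g * (p - t) / z.size)

    return _make(data, (logits,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling / normalization
# ---------------------------------------------------------------------------

def conv1d(x, w, b, pad: int = 0):
    """1-D convolution, stride 1.  x: (B, C, T); w: (O, C, K); b: (O,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, C, T = x.data.shape
    O, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B, C, T_out, K)
    # (O,) x (B, T_out) contraction over C, K
    out = np.tensordot(win, w.data, axes=([1, 3], [1, 2]))  # (B, T_out, O)
    out = np.ascontiguousarray(out.transpose(0, 2, 1)) + b.data[None, :, None]

    def backward(g):
        # g: (B, O, T_out)
        gw = np.tensordot(g, win, axes=([0, 2], [0, 2]))  # (O, C, K)
        gb = g.sum(axis=(0, 2))
        # dx: full correlation of g with w
        gp = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)  # (B, O, T+2p, K)
        wf = w.data[:, :, ::-1]
        gx_full = np.tensordot(gwin, wf, axes=([1, 3], [0, 2]))  # (B, T+2p, C)
        gx_full = gx_full.transpose(0, 2, 1)
        gx = gx_full[:, :, pad:pad + T] if pad else gx_full
        _accum(x, np.ascontiguousarray(gx))
        _accum(w, gw.astype(w.data.dtype))
        _accum(b, gb.astype(b.data.dtype))

    return _make(out, (x, w, b), backward)


def maxpool1d(x, kernel: int, stride: int = 1, pad: int = 0):
    """1-D max pooling over the last axis of (B, C, T)."""
    x = _as_tensor(x)
    B, C, T = x.data.shape
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)), constant_values=-np.inf)
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)[:, :, ::stride]
    arg = win.argmax(axis=3)  # (B, C, T_out)
    data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
    T_out = data.shape[2]
    starts = stride * np.arange(T_out) - pad
    src = starts[None, None, :] + arg  # index into unpadded x (argmax never at -inf pad)

    def backward(g):
        gx = np.zeros_like(x.data)
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        np.add.at(gx, (bidx, cidx, src), g)
        _accum(x, gx)

    return _make(np.ascontiguousarray(data), (x,), backward)


_BN_EPS = 1e-5


def batchnorm_train(x, gamma, beta, axes):
    """Batch normalization (training statistics).

    Normalizes over `axes` (e.g. (0, 2) for (B, C, T) per-channel, (0,) for
    (B, F)).  Returns (out, batch_mean, batch_var); the caller owns running
    statistics.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x.data - mu) * inv
    pshape = mu.shape  # broadcastable parameter shape
    gam = gamma.data.reshape(pshape)
    data = xhat * gam + beta.data.reshape(pshape)
    n = np.prod([x.data.shape[ax] for ax in axes])

    def backward(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        gxhat = g * gam
        gx = (inv / n) * (n * gxhat
                          - gxhat.sum(axis=axes, keepdims=True)
                          - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True))
        _accum(x, gx.astype(x.data.dtype))
        _accum(gamma, ggamma.reshape(gamma.data.shape).astype(gamma.data.dtype))
        _accum(beta, gbeta.reshape(beta.data.shape).astype(beta.data.dtype))

    return _make(data, (x, gamma, beta), backward), mu.squeeze(), var.squeeze()


def batchnorm_eval(x, gamma, beta, running_mean, running_var, axes):
    """Batch normalization with frozen (running) statistics."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    pshape = [1] * x.data.ndim
    for ax in range(x.data.ndim):
        if ax not in axes:
            pshape[ax] = x.data.shape[ax]
    rm = np.asarray(running_mean).reshape(pshape)
    rv = np.asarray(running_var).reshape(pshape)
    inv = 1.0 / np.sqrt(rv + _BN_EPS)
    gam = gamma.data.reshape(pshape)
    data = (x.data - rm) * inv * gam + beta.data.reshape(pshape)

    def backward(g):
        _accum(x, (g * inv * gam).astype(x.data.dtype))
        _accum(gamma, ((g * (x.data - rm) * inv).sum(axis=tuple(axes))
                       ).reshape(gamma.data.shape).astype(gamma.data.dtype))
        _accum(beta, g.sum(axis=tuple(axes)).reshape(beta.data.shape).astype(beta.data.dtype))

    return _make(data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# recurrent layers (fused over the full sequence)
# ---------------------------------------------------------------------------

def lstm(x, w, u, b):
    """Single LSTM layer over a batch-first sequence.

    x: (B, T, I); w: (I, 4H); u: (H, 4H); b: (4H,).  Gate order i, f, g, o.
    Returns the full hidden sequence (B, T, H).
    """
    x, w, u, b = _as_tensor(x), _as_tensor(w), _as_tensor(u), _as_tensor(b)
    B, T, I = x.data.shape
    H = u.data.shape[0]
    dtype = x.data.dtype
    xw = x.data.reshape(B * T, I) @ w.data
    xw = xw.reshape(B, T, 4 * H) + b.data

    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    hs = np.empty((B, T, H), dtype=dtype)
    cache_i = np.empty((B, T, H), dtype=dtype)
    cache_f = np.empty((B, T, H), dtype=dtype)
    cache_g = np.empty((B, T, H), dtype=dtype)
    cache_o = np.empty((B, T, H), dtype=dtype)
    cache_ct = np.empty((B, T, H), dtype=dtype)
    cache_cprev = np.empty((B, T, H), dtype=dtype)
    for t in range(T):
        a = xw[:, t] + h @ u.data
        i_g = _sigmoid(a[:, :H])
        f_g = _sigmoid(a[:, H:2 * H])
        g_g = np.tanh(a[:, 2 * H:3 * H])
        o_g = _sigmoid(a[:, 3 * H:])
        cache_cprev[:, t] = c
        c = f_g * c + i_g * g_g
        ct = np.tanh(c)
        h = o_g * ct
        hs[:, t] = h
        cache_i[:, t] = i_g
        cache_f[:, t] = f_g
        cache_g[:, t] = g_g
        cache_o[:, t] = o_g
        cache_ct[:, t] = ct

    def backward(gh_seq):
        gw = np.zeros_like(w.data)
        gu = np.zeros_like(u.data)
        gb = np.zeros_like(b.data)
        gx = np.empty_like(x.data)
        da_all = np.empty((B, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            dh = gh_seq[:, t] + dh_next
            i_g, f_g, g_g, o_g = cache_i[:, t], cache_f[:, t], cache_g[:, t], cache_o[:, t]
            ct = cache_ct[:, t]
            do = dh * ct
            dc = dh * o_g * (1 - ct * ct) + dc_next
            di = dc * g_g
            df = dc * cache_cprev[:, t]
            dg = dc * i_g
            da = np.concatenate([
                di * i_g * (1 - i_g),
                df * f_g * (1 - f_g),
                dg * (1 - g_g * g_g),
                do * o_g * (1 - o_g),
            ], axis=1)
            da_all[:, t] = da
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            gu += h_prev.T @ da
            dh_next = da @ u.data.T
            dc_next = dc * f_g
        da_flat = da_all.reshape(B * T, 4 * H)
        gw += x.data.reshape(B * T, I).T @ da_flat
        gb += da_flat.sum(axis=0)
        gx[:] = (da_flat @ w.data.T).reshape(B, T, I)
        _accum(x, gx)
        _accum(w, gw)
        _accum(u, gu)
        _accum(b, gb)

    return _make(hs, (x, w, u, b), backward)


def gru(x, w, u, bx, bh):
    """Single GRU layer over a batch-first sequence.

    x: (B, T, I); w: (I, 3H); u: (H, 3H); bx, bh: (3H,).  Gate order r, z, n;
    candidate uses n = tanh(x Wn + bxn + r * (h Un + bhn)).
    """
    x, w, u = _as_tensor(x), _as_tensor(w), _as_tensor(u)
    bx, bh = _as_tensor(bx), _as_tensor(bh)
    B, T, I = x.data.shape
    H = u.data.shape[0]
    dtype = x.data.dtype
    xw = x.data.reshape(B * T, I) @ w.data
    xw = xw.reshape(B, T, 3 * H) + bx.data

    h = np.zeros((B, H), dtype=dtype)
    hs = np.empty((B, T, H), dtype=dtype)
    c_r = np.empty((B, T, H), dtype=dtype)
    c_z = np.empty((B, T, H), dtype=dtype)
    c_n = np.empty((B, T, H), dtype=dtype)
    c_hu = np.empty((B, T, H), dtype=dtype)  # h @ Un + bhn
    for t in range(T):
        hu = h @ u.data + bh.data
        r = _sigmoid(xw[:, t, :H] + hu[:, :H])
        z = _sigmoid(xw[:, t, H:2 * H] + hu[:, H:2 * H])
        hun = hu[:, 2 * H:]
        n = np.tanh(xw[:, t, 2 * H:] + r * hun)
        c_r[:, t], c_z[:, t], c_n[:, t], c_hu[:, t] = r, z, n, hun
        h = (1 - z) * n + z * h
        hs[:, t] = h

    def backward(gh_seq):
        gw = np.zeros_like(w.data)
        gu = np.zeros_like(u.data)
        gbx = np.zeros_like(bx.data)
        gbh = np.zeros_like(bh.data)
        gx = np.empty_like(x.data)
        da_all = np.empty((B, T, 3 * H), dtype=dtype)  # grads w.r.t. xw rows
        dh_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            dh = gh_seq[:, t] + dh_next
            r, z, n, hun = c_r[:, t], c_z[:, t], c_n[:, t], c_hu[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            dn = dh * (1 - z)
            dz = dh * (h_prev - n)
            dan = dn * (1 - n * n)          # pre-tanh
            dr = dan * hun
            dhun = dan * r
            dar = dr * r * (1 - r)          # pre-sigmoid r
            daz = dz * z * (1 - z)          # pre-sigmoid z
            da = np.concatenate([dar, daz, dan], axis=1)
            da_all[:, t] = da
            # hu = h_prev @ U + bh receives [dar, daz, dhun]
            dhu = np.concatenate([dar, daz, dhun], axis=1)
            gu += h_prev.T @ dhu
            gbh += dhu.sum(axis=0)
            dh_next = dh * z + dhu @ u.data.T
        da_flat = da_all.reshape(B * T, 3 * H)
        gw += x.data.reshape(B * T, I).T @ da_flat
        gbx += da_flat.sum(axis=0)
        gx[:] = (da_flat @ w.data.T).reshape(B, T, I)
        _accum(x, gx)
        _accum(w, gw)
        _accum(u, gu)
        _accum(bx, gbx)
        _accum(bh, gbh)

    return _make(hs, (x, w, u, bx, bh), backward)


def reverse_time(x, lengths):
    """Reverse the first `lengths[i]` steps of each (B, T, I) sequence.

    Trailing padding stays in place, so a backward-direction RNN starts at
    the last valid sample.  The map is an involutive permutation; backward
    applies the same permutation to the gradient.
    """
    x = _as_tensor(x)
    B, T, _ = x.data.shape
    lengths = np.asarray(lengths, dtype=np.intp)
    idx = np.tile(np.arange(T), (B, 1))
    for i, L in enumerate(lengths):
        idx[i, :L] = np.arange(L - 1, -1, -1)
    rows = np.arange(B)[:, None]
    data = x.data[rows, idx]

    def backward(g):
        _accum(x, g[rows, idx])

    return _make(np.ascontiguousarray(data), (x,), backward)
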