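"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the leaf-maturity network needs:
dense/conv/depthwise-conv layers (NHWC layout), batch normalization,
ReLU/sigmoid, separable bilinear resampling, channelwise reductions,
concatenation and a fused softmax cross-entropy.  Gradients flow through
a dynamically built tape (topological sort over a DAG), micrograd-style
but on whole arrays.

Convolutions are evaluated by im2col + BLAS matmul; their input
gradients are scattered back with a short loop over the (small) kernel
footprint, which keeps every inner operation vectorized.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference / masked forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this node through the tape."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward):
    """Create a result node, attaching the tape edge only when needed."""
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (reverse of NumPy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- arithmetic -----------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def reshape(x, shape):
    x = _as_tensor(x)
    orig = x.data.shape
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _make(data, (x,), backward)


# -- activations ----------------------------------------------------------

def relu(x):
    x = _as_tensor(x)
    data = np.maximum(x.data, 0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return _make(data, (x,), backward)


def sigmoid(x):
    from scipy.special import expit

    x = _as_tensor(x)
    data = expit(x.data)

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _make(data, (x,), backward)


# -- reductions -----------------------------------------------------------

def global_avg_pool(x):
    """[N,H,W,C] -> [N,C] spatial mean."""
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    data = x.data.mean(axis=(1, 2))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, None, None, :] / (h * w), x.data.shape))

    return _make(data, (x,), backward)


def channel_mean(x):
    """[N,H,W,C] -> [N,H,W,1] mean over channels."""
    x = _as_tensor(x)
    c = x.data.shape[-1]
    data = x.data.mean(axis=-1, keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / c, x.data.shape))

    return _make(data, (x,), backward)


def channel_max(x):
    """[N,H,W,C] -> [N,H,W,1] max over channels (grad to first argmax)."""
    x = _as_tensor(x)
    idx = x.data.argmax(axis=-1, keepdims=True)
    data = np.take_along_axis(x.data, idx, axis=-1)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=-1)
        x._accumulate(gx)

    return _make(data, (x,), backward)


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(data, tuple(tensors), backward)


# -- convolutions (NHWC) --------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Standard convolution. x:[N,H,W,Cin], w:[kh,kw,Cin,Cout], b:[Cout]|None."""
    x, w = _as_tensor(x), _as_tensor(w)
    kh, kw, cin, cout = w.data.shape
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[-1]}, kernel expects {cin}"
        )
    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b)
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
    # win: [N, Ho, Wo, Cin, kh, kw] -> patches [N*Ho*Wo, kh*kw*Cin]
    n, ho, wo = win.shape[:3]
    patches = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * cin
    )
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = patches @ wmat
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data
    data = out.reshape(n, ho, wo, cout)

    def backward(g):
        gmat = g.reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accumulate((patches.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
            hp, wp = xp.shape[1], xp.shape[2]
            gxp = np.zeros((n, hp, wp, cin), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + s * ho : s, j : j + s * wo : s] += gcols[:, :, :, i, j]
            gx = gxp[:, p : hp - p, p : wp - p] if p else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def _conv1x1(x, w, b):
    """Pointwise convolution as a single BLAS matmul (no im2col)."""
    cin, cout = w.data.shape[2], w.data.shape[3]
    n, h, ww_, _ = x.data.shape
    xmat = x.data.reshape(n * h * ww_, cin)
    wmat = w.data.reshape(cin, cout)
    out = xmat @ wmat
    if b is not None:
        b = _as_tensor(b)
        out += b.data
    data = out.reshape(n, h, ww_, cout)

    def backward(g):
        gmat = g.reshape(n * h * ww_, cout)
        if w.requires_grad:
            w._accumulate((xmat.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            x._accumulate((gmat @ wmat.T).reshape(x.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def depthwise_conv2d(x, w, stride: int = 1, padding: int = 0):
    """Depthwise convolution. x:[N,H,W,C], w:[kh,kw,C]; one filter per channel."""
    x, w = _as_tensor(x), _as_tensor(w)
    kh, kw, c = w.data.shape
    if x.data.shape[-1] != c:
        raise ValueError(
            f"depthwise_conv2d channel mismatch: input {x.data.shape[-1]} vs kernel {c}"
        )
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    n, hp, wp, _ = xp.shape
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    # accumulate over the small kernel footprint with strided views;
    # avoids materializing the [N,Ho,Wo,C,kh,kw] window tensor
    data = np.zeros((n, ho, wo, c), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            data += xp[:, i : i + s * ho : s, j : j + s * wo : s] * w.data[i, j]

    def backward(g):
        if w.requires_grad:
            gw = np.empty((kh, kw, c), dtype=w.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j] = (xp[:, i : i + s * ho : s, j : j + s * wo : s] * g).sum(
                        axis=(0, 1, 2)
                    )
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros((n, hp, wp, c), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + s * ho : s, j : j + s * wo : s] += g * w.data[i, j]
            gx = gxp[:, p : hp - p, p : wp - p] if p else gxp
            x._accumulate(gx)

    return _make(data, (x, w), backward)


# -- batch normalization --------------------------------------------------

def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.9, eps: float = 1e-3):
    """Batch normalization over (N,H,W) per channel.

    `running_mean`/`running_var` are plain arrays mutated in place during
    training (they carry no gradient, but count as model parameters).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        xhat = x.data - mean            # centered copy, becomes xhat in place
        var = np.mean(np.square(xhat), axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat *= inv_std
    else:
        inv_std = 1.0 / np.sqrt(running_var + eps)
        xhat = (x.data - running_mean) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            if training:
                m = np.prod([x.data.shape[a] for a in axes])
                gs = g.sum(axis=axes)
                gxs = (g * xhat).sum(axis=axes)
                gx = xhat * (gxs / m)
                gx += gs / m
                gx = g - gx
                gx *= gamma.data * inv_std
                x._accumulate(gx)
            else:
                x._accumulate(g * (gamma.data * inv_std))

    return _make(data, (x, gamma, beta), backward)


# -- bilinear resampling --------------------------------------------------

def resize_matrix(n_src: int, n_dst: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers).

    Sample i of the destination reads source coordinate
    (i + 0.5) * n_src / n_dst - 0.5, clamped to the valid range; this is
    the align-corners-off convention shared by the data pipeline and the
    pyramid upsampler.
    """
    m = np.zeros((n_dst, n_src), dtype=dtype)
    scale = n_src / n_dst
    for i in range(n_dst):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_src - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_src - 1)
        t = src - i0
        m[i, i0] += 1.0 - t
        m[i, i1] += t
    return m


def bilinear_resize(x, out_h: int, out_w: int):
    """Separable bilinear resize of [N,H,W,C] to [N,out_h,out_w,C]."""
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    ah = resize_matrix(h, out_h, dtype=x.data.dtype)
    aw = resize_matrix(w, out_w, dtype=x.data.dtype)
    tmp = np.einsum("oh,nhwc->nowc", ah, x.data, optimize=True)
    data = np.einsum("pw,nowc->nopc", aw, tmp, optimize=True)

    def backward(g):
        t = np.einsum("pw,nopc->nowc", aw, g, optimize=True)
        x._accumulate(np.einsum("oh,nowc->nhwc", ah, t, optimize=True))

    return _make(data, (x,), backward)


# -- losses ---------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-array softmax (inference utility, no tape)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean categorical cross-entropy. logits:[N,K], labels: int array [N]."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    p = softmax(logits.data)
    eps = np.finfo(p.dtype).tiny
    data = np.array(-np.log(p[np.arange(n), labels] + eps).mean(), dtype=logits.data.dtype)

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return _make(data, (logits,), backward)
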