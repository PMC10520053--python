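"""Reverse-mode automatic differentiation on float32 numpy arrays.

The package trains small convolutional/recurrent models; this module
provides the tape that makes that possible: a :class:`Tensor` wrapping an
``ndarray`` plus backward closures for the handful of operations the models
need (dense/convolutional algebra, pointwise nonlinearities, pooling,
batch normalisation, dropout, the spike nonlinearity with its surrogate
derivative, and the two cross-entropy losses).

Everything is float32 by default (the :func:`precision` context switches to
float64 for tight numerical checks); convolutions are evaluated as batched
GEMMs over im2col views and are internally chunked over the batch so peak
memory stays bounded for 80x80 inputs.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
import scipy.fft as sfft

DTYPE = np.dtype(np.float32)


@contextmanager
def precision(dtype):
    """Temporarily switch the dtype newly created tensors use."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DTYPE = old


__all__ = [
    "Tensor", "precision", "DTYPE",
    "add", "sub", "mul", "neg", "matmul", "reshape", "broadcast_to",
    "concat", "relu", "sigmoid", "tanh", "log", "clip", "spike",
    "reduce_sum", "reduce_mean", "dropout", "conv2d_valid", "maxpool2x2",
    "batchnorm", "take_rows", "softmax", "softmax_cross_entropy",
]


class Tensor:
    """A node in the autodiff graph: float32 data plus an optional gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from absorbing Tensors in mixed ndarray-Tensor arithmetic
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis=axis, keepdims=keepdims)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph bookkeeping and intermediate gradients as we
                # go; leaf parameters (no backward closure) keep .grad
                node._backward = None
                node._parents = ()
                node.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        # own the memory: closures may hand the same array to two parents
        t.grad = np.array(g, dtype=DTYPE)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))
    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, -g)
    return _make(-a.data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            _accum(a, g @ b.data.T)
        if b.requires_grad:
            _accum(b, a.data.T @ g)
    return _make(a.data @ b.data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        _accum(a, g.reshape(old))
    return _make(a.data.reshape(shape), (a,), backward)


def broadcast_to(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        _accum(a, _unbroadcast(g, old))
    return _make(np.broadcast_to(a.data, shape), (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        _accum(a, g * (out_data > 0))
    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided form
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))
    return _make(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))
    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / a.data)
    return _make(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accum(a, g * inside)
    return _make(np.clip(a.data, lo, hi), (a,), backward)


def spike(a: Tensor) -> Tensor:
    """Heaviside step with a sigmoid-derivative surrogate gradient.

    Forward emits binary spikes Theta(v); backward uses sigma'(v), the
    pseudo-derivative that makes spiking layers trainable by
    backpropagation through time.
    """
    out_data = (a.data > 0).astype(DTYPE)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -30, 30)))
        _accum(a, g * s * (1.0 - s))
    return _make(out_data, (a,), backward)


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).astype(DTYPE))
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape).astype(DTYPE))
    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / n, a.data.shape).astype(DTYPE))
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gg / n, a.data.shape).astype(DTYPE))
    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------

def dropout(a: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not train or rate <= 0.0:
        return a
    keep = 1.0 - rate
    u = rng.random(a.data.shape, dtype=np.float32)
    mask = u < keep                 # boolean mask: 4x smaller than float
    scale = DTYPE.type(1.0 / keep)
    out = a.data * mask
    out *= scale

    def backward(g):
        dg = g * mask
        dg *= scale
        _accum(a, dg)
    return _make(out, (a,), backward)


def conv2d_valid(x: Tensor, w: Tensor) -> Tensor:
    """Valid (no padding, stride 1) 2-D cross-correlation, NCHW layout.

    ``w`` has shape (C_out, C_in, kh, kw). Evaluated through real 2-D FFTs
    of size (H, W): circular correlation equals the linear one at the valid
    shifts, and the channel contraction becomes a batched GEMM over
    frequency bins. The forward pass caches the input spectrum so the
    backward pass (a full convolution for the input gradient, a batch
    correlation for the weight gradient) reuses it.
    """
    b, c, h, wd = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cin}")
    ho, wo = h - kh + 1, wd - kw + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"conv2d: kernel {kh}x{kw} larger than input {h}x{wd}")
    nf = h * (wd // 2 + 1)
    xf = sfft.rfft2(x.data, s=(h, wd))                       # (B, Cin, h, wd//2+1)
    wf = sfft.rfft2(w.data, s=(h, wd))                       # (Cout, Cin, h, ...)
    xf2 = np.ascontiguousarray(xf.reshape(b, cin, nf).transpose(2, 0, 1))   # (F,B,Cin)
    wf2 = np.ascontiguousarray(np.conj(wf).reshape(cout, cin, nf).transpose(2, 1, 0))
    of = np.matmul(xf2, wf2)                                 # (F, B, Cout)
    of = of.transpose(1, 2, 0).reshape(b, cout, h, wd // 2 + 1)
    out = sfft.irfft2(of, s=(h, wd))[..., :ho, :wo].astype(DTYPE)

    def backward(g):
        gpad = np.zeros((b, cout, h, wd), dtype=DTYPE)
        gpad[..., :ho, :wo] = g
        gf = sfft.rfft2(gpad, s=(h, wd))
        gf2 = np.ascontiguousarray(gf.reshape(b, cout, nf).transpose(2, 0, 1))  # (F,B,Cout)
        if w.requires_grad:
            # dW = batch correlation of x with g, cropped to the kernel
            dwf = np.matmul(np.conj(gf2).transpose(0, 2, 1), xf2)   # (F, Cout, Cin)
            dwf = dwf.transpose(1, 2, 0).reshape(cout, cin, h, wd // 2 + 1)
            dw = sfft.irfft2(dwf, s=(h, wd))[..., :kh, :kw]
            _accum(w, dw.astype(DTYPE))
        if x.requires_grad:
            # dX = full convolution of g with the (unflipped) kernel
            dxf = np.matmul(gf2, np.conj(wf2).transpose(0, 2, 1))   # (F, B, Cin)
            dxf = dxf.transpose(1, 2, 0).reshape(b, cin, h, wd // 2 + 1)
            _accum(x, sfft.irfft2(dxf, s=(h, wd)).astype(DTYPE))
    return _make(out, (x, w), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims)."""
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        _accum(x, dx)
    return _make(out, (x,), backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              train: bool, momentum: float = 0.99, eps: float = 1e-3,
              fuse_relu: bool = False) -> Tensor:
    """Batch normalisation over all axes except channel axis 1 (NCHW).

    ``running`` is a dict with keys ``mean``/``var`` mutated in training mode;
    inference mode normalises with the stored running statistics.
    ``fuse_relu`` applies the rectifier in the same op (one fewer stored
    activation on the tape).
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, x.data.shape[1]) + (1,) * (x.data.ndim - 2)
    n = x.data.size // x.data.shape[1]

    def _csum(arr):
        # per-channel reduction without large temporaries
        return arr.sum(axis=axes)

    def _cdot(a1, a2):
        if a1.ndim == 4:
            return np.einsum("bchw,bchw->c", a1, a2, optimize=True)
        return (a1 * a2).sum(axis=axes)

    if train:
        s1 = _csum(x.data)
        s2 = _cdot(x.data, x.data)
        mean = s1 / n
        var = np.maximum(s2 / n - mean * mean, 0.0)
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    inv = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - mean.reshape(bshape).astype(DTYPE))
    xhat *= inv.reshape(bshape)
    out = xhat * gamma.data.reshape(bshape)
    out += beta.data.reshape(bshape)
    if fuse_relu:
        np.maximum(out, 0.0, out=out)

    def backward(g):
        if fuse_relu:
            g = g * (out > 0)
        if gamma.requires_grad:
            _accum(gamma, _cdot(g, xhat).astype(DTYPE))
        if beta.requires_grad:
            _accum(beta, _csum(g).astype(DTYPE))
        if x.requires_grad:
            k1 = gamma.data * inv                   # (C,)
            if train:
                gsum = _csum(g)
                gxsum = _cdot(g, xhat)
                dx = g * k1.reshape(bshape)
                dx -= xhat * ((k1 * gxsum / n).reshape(bshape))
                dx -= (k1 * gsum / n).reshape(bshape)
                _accum(x, dx)
            else:
                _accum(x, g * k1.reshape(bshape))
    return _make(out, (x, gamma, beta), backward)


def take_rows(emb: Tensor, idx: np.ndarray) -> Tensor:
    """Per-sample row selection: (B,K,D) indexed by (B,) -> (B,D)."""
    b = emb.data.shape[0]
    rows = np.arange(b)
    out = emb.data[rows, idx]

    def backward(g):
        demb = np.zeros_like(emb.data)
        demb[rows, idx] = g  # each batch row selected once: no collisions
        _accum(emb, demb)
    return _make(out, (emb,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        _accum(a, p * (g - (g * p).sum(axis=axis, keepdims=True)))
    return _make(p, (a,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of integer ``labels`` under ``logits``."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    b = logits.data.shape[0]
    nll = -np.log(np.maximum(p[np.arange(b), labels], 1e-30)).mean()

    def backward(g):
        dp = p.copy()
        dp[np.arange(b), labels] -= 1.0
        _accum(logits, (g * dp / b).astype(DTYPE))
    return _make(nll, (logits,), backward)
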