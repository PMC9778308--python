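"""Minimal reverse-mode autodiff on numpy arrays, with the layers and the
Adam optimizer used by the frequency-spatial-temporal model.

The engine is a tape of :class:`Tensor` nodes; every operation records a
closure that accumulates gradients into its parents.  Only the operations
the model needs are provided: broadcast arithmetic, matmul, stride-1
"same"-padded 2D convolution (full and depthwise), 2x2/stride-2 max
pooling with -inf edge padding for odd extents, batch normalization,
sigmoid / tanh / ReLU, softmax, directional cumulative sums (the ordered-
neuron master gates), slicing, and a fused softmax cross-entropy loss.
Gradients of every op are checked against central finite differences in
the test suite.

All floating work is float32 for speed; accumulation in the loss uses
float64.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "parameter",
    "add", "sub", "mul", "matmul",
    "relu", "sigmoid", "tanh", "softmax",
    "cumsum", "reshape", "transpose", "getitem", "concat",
    "conv2d", "depthwise_conv2d", "maxpool2x2", "batchnorm", "dense",
    "softmax_cross_entropy",
    "BatchNormState", "Adam",
]

_DT = np.float32


class Tensor:
    """A node in the autodiff tape wrapping one numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[], None]] = None,
    ):
        self.data = np.asarray(data, dtype=_DT)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # first contribution is adopted (may alias the producer's buffer);
        # later contributions rebind, so the alias is never mutated
        g = g.astype(_DT, copy=False)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def _accum_at(self, idx, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[idx] += g.astype(_DT, copy=False)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() starts from a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # this node's gradient, closure and parent links are no
                # longer needed: drop them so large intermediates die by
                # refcount as the sweep proceeds
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # convenience operator sugar
    def __add__(self, other): return add(self, _wrap(other))
    def __radd__(self, other): return add(_wrap(other), self)
    def __sub__(self, other): return sub(self, _wrap(other))
    def __rsub__(self, other): return sub(_wrap(other), self)
    def __mul__(self, other): return mul(self, _wrap(other))
    def __rmul__(self, other): return mul(_wrap(other), self)
    def __neg__(self): return mul(self, _wrap(np.float32(-1.0)))
    def __matmul__(self, other): return matmul(self, other)
    def __getitem__(self, idx): return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DT))


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise & linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad, b.shape))

    out._backward = bw if out.requires_grad else None
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def bw(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accum(-_unbroadcast(grad, b.shape))

    out._backward = bw if out.requires_grad else None
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad * a.data, b.shape))

    out._backward = bw if out.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(grad):
        if a.requires_grad:
            a._accum(grad @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ grad)

    out._backward = bw if out.requires_grad else None
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.maximum(x.data, 0), parents=(x,))

    def bw(grad):
        x._accum(grad * mask)

    out._backward = bw if out.requires_grad else None
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = _expit(x.data)
    out = Tensor(y, parents=(x,))

    def bw(grad):
        x._accum(grad * y * (1.0 - y))

    out._backward = bw if out.requires_grad else None
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def bw(grad):
        x._accum(grad * (1.0 - y * y))

    out._backward = bw if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(grad):
        g = grad
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw if out.requires_grad else None
    return out


def cumsum(x: Tensor, axis: int = -1, reverse: bool = False) -> Tensor:
    """Directional cumulative sum (``reverse=True`` sums right-to-left)."""
    if reverse:
        y = np.flip(np.cumsum(np.flip(x.data, axis=axis), axis=axis), axis=axis)
    else:
        y = np.cumsum(x.data, axis=axis)
    out = Tensor(y, parents=(x,))

    def bw(grad):
        g = grad
        if reverse:
            gx = np.cumsum(g, axis=axis)
        else:
            gx = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
        x._accum(gx)

    out._backward = bw if out.requires_grad else None
    return out


def reshape(x: Tensor, shape: Tuple[int, ...]) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bw(grad):
        x._accum(grad.reshape(x.shape))

    out._backward = bw if out.requires_grad else None
    return out


def transpose(x: Tensor, axes: Tuple[int, ...]) -> Tensor:
    out = Tensor(np.ascontiguousarray(x.data.transpose(axes)), parents=(x,))
    inv = tuple(np.argsort(axes))

    def bw(grad):
        x._accum(grad.transpose(inv))

    out._backward = bw if out.requires_grad else None
    return out


def getitem(x: Tensor, idx) -> Tensor:
    out = Tensor(x.data[idx], parents=(x,))

    def bw(grad):
        g = np.zeros_like(x.data)
        np.add.at(g, idx, grad)
        x._accum(g)

    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=tuple(ts))
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(grad):
        parts = np.split(grad, splits, axis=axis)
        for t, g in zip(ts, parts):
            if t.requires_grad:
                t._accum(g)

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# convolution / pooling / normalization
# ---------------------------------------------------------------------------

def _same_pad(x: np.ndarray, kh: int, kw: int, value: float = 0.0) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)), constant_values=value)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 zero-padded ("same") 2D convolution with odd kernels.

    ``x`` (B, H, W, C_in); ``w`` (kh, kw, C_in, C_out); ``b`` (C_out,).
    Implemented as a sum of shifted matmuls over kernel offsets, which keeps
    the channel axis contiguous.
    """
    kh, kw, c, o = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("same-padded convolution requires odd kernel sizes")
    if x.shape[3] != c:
        raise ValueError(f"input has {x.shape[3]} channels, kernel expects {c}")
    bb, h, ww, _ = x.shape
    xp = _same_pad(x.data, kh, kw)
    w2 = w.data.reshape(kh * kw * c, o)
    if kh == 1 and kw == 1:
        cols = xp.reshape(bb * h * ww, c)
    else:
        # im2col: one contiguous (BHW, kh*kw*C) patch matrix -> single gemm
        cols = np.empty((bb, h, ww, kh * kw * c), dtype=_DT)
        for i in range(kh):
            for j in range(kw):
                k = (i * kw + j) * c
                cols[..., k : k + c] = xp[:, i : i + h, j : j + ww, :]
        cols = cols.reshape(bb * h * ww, kh * kw * c)
    y = (cols @ w2).reshape(bb, h, ww, o) + b.data
    out = Tensor(y, parents=(x, w, b))

    def bw(grad):
        g2 = grad.reshape(-1, o)
        if w.requires_grad:
            w._accum((cols.T @ g2).reshape(kh, kw, c, o))
        if b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            gc = (g2 @ w2.T).reshape(bb, h, ww, kh * kw * c)
            if kh == 1 and kw == 1:
                x._accum(gc)
            else:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        k = (i * kw + j) * c
                        gxp[:, i : i + h, j : j + ww, :] += gc[..., k : k + c]
                ph, pw = kh // 2, kw // 2
                x._accum(gxp[:, ph : ph + h, pw : pw + ww, :])

    out._backward = bw if out.requires_grad else None
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Depthwise stride-1 same convolution (depth multiplier 1).

    ``x`` (B, H, W, C); ``w`` (kh, kw, C); ``b`` (C,): one spatial filter
    per input map, no cross-channel mixing.
    """
    kh, kw, c = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("same-padded convolution requires odd kernel sizes")
    if x.shape[3] != c:
        raise ValueError(f"input has {x.shape[3]} channels, depthwise kernel expects {c}")
    bb, h, ww, _ = x.shape
    xp = _same_pad(x.data, kh, kw)
    y = np.zeros((bb, h, ww, c), dtype=_DT)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, i : i + h, j : j + ww, :] * w.data[i, j]
    y += b.data
    out = Tensor(y, parents=(x, w, b))

    def bw(grad):
        g = grad
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad:
                    w._accum_at(
                        (i, j), (xp[:, i : i + h, j : j + ww, :] * g).sum(axis=(0, 1, 2))
                    )
                if gxp is not None:
                    gxp[:, i : i + h, j : j + ww, :] += g * w.data[i, j]
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if gxp is not None:
            ph, pw = kh // 2, kw // 2
            x._accum(gxp[:, ph : ph + h, pw : pw + ww, :])

    out._backward = bw if out.requires_grad else None
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; odd extents are padded with -inf."""
    b, h, w, c = x.shape
    ph, pw = h % 2, w % 2
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
    h2, w2 = xp.shape[1] // 2, xp.shape[2] // 2
    blocks = np.ascontiguousarray(
        xp.reshape(b, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    ).reshape(b, h2, w2, c, 4)
    arg = blocks.argmax(axis=-1)
    y = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def bw(grad):
        g = np.zeros_like(blocks)
        np.put_along_axis(g, arg[..., None], grad[..., None], axis=-1)
        g = g.reshape(b, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            b, h2 * 2, w2 * 2, c
        )
        x._accum(g[:, :h, :w, :])

    out._backward = bw if out.requires_grad else None
    return out


class BatchNormState:
    """Running mean/variance for one batch-normalization layer."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.mean = np.zeros(n_features, dtype=_DT)
        self.var = np.ones(n_features, dtype=_DT)
        self.momentum = momentum
        self.eps = eps


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, state: BatchNormState,
              training: bool) -> Tensor:
    """Batch normalization over the trailing channel axis.

    ``x`` is (B, H, W, C) or (B, C).  Training mode normalizes with batch
    statistics and updates the running averages; evaluation mode uses the
    running averages.
    """
    axes = (0, 1, 2) if x.data.ndim == 4 else (0,)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = state.momentum
        state.mean = m * state.mean + (1 - m) * mean.astype(_DT)
        state.var = m * state.var + (1 - m) * var.astype(_DT)
    else:
        mean, var = state.mean, state.var
    inv_std = (1.0 / np.sqrt(var + state.eps)).astype(_DT)
    xhat = (x.data - mean) * inv_std
    y = gamma.data * xhat + beta.data
    out = Tensor(y, parents=(x, gamma, beta))
    n = x.data.size // x.data.shape[-1]

    def bw(grad):
        g = grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data
            if training:
                s1 = gs.sum(axis=axes, keepdims=True)
                s2 = (gs * xhat).sum(axis=axes, keepdims=True)
                gx = inv_std * (gs - s1 / n - xhat * s2 / n)
            else:
                gx = gs * inv_std
            x._accum(gx)

    out._backward = bw if out.requires_grad else None
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine layer ``x @ w + b`` with ``x`` (B, in), ``w`` (in, out)."""
    return add(matmul(x, w), b)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) vs integer labels."""
    y = np.asarray(labels, dtype=np.intp)
    z = logits.data.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = z.shape[0]
    loss = -logp[np.arange(n), y].mean()
    out = Tensor(np.asarray(loss), parents=(logits,))

    def bw(grad):
        p = np.exp(logp)
        p[np.arange(n), y] -= 1.0
        logits._accum(grad * (p / n).astype(_DT))

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard moment defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.003,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
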