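"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the segmentation network needs: broadcasted
arithmetic, ReLU/sigmoid, reductions, channel concatenation, (log)softmax,
same-padded 3D convolution (im2col + BLAS matmul, with the data gradient
computed as a convolution with flipped kernels), 2x max pooling and 2x
nearest-neighbour upsampling.  Tensors are channel-first:
``(batch, channels, x, y, z)``.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    def backward(self, grad=None):
        """Accumulate gradients into every upstream tensor with
        ``requires_grad`` set."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g
            # free non-leaf intermediates
            if node._parents:
                node.grad = None

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise arithmetic


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    return Tensor(
        out_data,
        parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.shape),
        ),
    )


def scale(a, c: float):
    a = as_tensor(a)
    return Tensor(a.data * c, parents=(a,), backward=lambda g: (g * c,))


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


def sigmoid(a):
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(y, parents=(a,), backward=lambda g: (g * y * (1.0 - y),))


# ---------------------------------------------------------------------------
# reductions and reshaping


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(axes):
                g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out, parents=(a,), backward=backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# softmax family


def softmax(a, axis=1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor(y, parents=(a,), backward=backward)


def log_softmax(a, axis=1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    lsm = z - lse
    p = np.exp(lsm)

    def backward(g):
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(lsm, parents=(a,), backward=backward)


# ---------------------------------------------------------------------------
# spatial ops


def _kernel_offsets(k: int):
    return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _shifted(xp: np.ndarray, off, spatial) -> np.ndarray:
    """Contiguous (N, C, V) copy of the padded input at one kernel offset."""
    dz, dy, dx = off
    D, H, W = spatial
    view = xp[:, :, dz : dz + D, dy : dy + H, dx : dx + W]
    return np.ascontiguousarray(view).reshape(xp.shape[0], xp.shape[1], D * H * W)


def _conv_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation as a sum of per-offset channel GEMMs.

    For each kernel offset a contiguous shifted copy of the input is
    multiplied by the (F, C) kernel slice and accumulated; this keeps every
    GEMM operand contiguous and avoids the k^3-fold im2col blow-up.
    """
    N, C, D, H, W = x.shape
    F, Cw, k = w.shape[0], w.shape[1], w.shape[2]
    if Cw != C:
        raise ValueError(f"conv expects {Cw} input channels, got {C}")
    V = D * H * W
    if k == 1:
        return np.matmul(w.reshape(F, C), x.reshape(N, C, V)).reshape(N, F, D, H, W)
    xp = _pad_same(x, k)
    wo = w.reshape(F, C, k**3)
    out = np.zeros((N, F, V), dtype=x.dtype)
    for o, off in enumerate(_kernel_offsets(k)):
        xs = _shifted(xp, off, (D, H, W))
        out += np.matmul(wo[:, :, o], xs)
    return out.reshape(N, F, D, H, W)


def _conv_weight_grad(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """dL/dw for a same-padded correlation, offset by offset (low memory)."""
    N, C, D, H, W = x.shape
    F = g.shape[1]
    V = D * H * W
    g_mat = g.reshape(N, F, V)
    if k == 1:
        return np.matmul(g_mat, x.reshape(N, C, V).transpose(0, 2, 1)).sum(axis=0).reshape(
            F, C, 1, 1, 1
        )
    xp = _pad_same(x, k)
    dw = np.empty((F, C, k**3), dtype=g.dtype)
    for o, off in enumerate(_kernel_offsets(k)):
        xs = _shifted(xp, off, (D, H, W))
        dw[:, :, o] = np.matmul(g_mat, xs.transpose(0, 2, 1)).sum(axis=0)
    return dw.reshape(F, C, k, k, k)


def conv3d(x, w, b=None):
    """Same-padded stride-1 3D convolution (cross-correlation).

    ``x``: (N, C, D, H, W); ``w``: (F, C, k, k, k) with odd k; ``b``: (F,).
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    out = _conv_forward(x.data, w.data)
    if b is not None:
        out = out + b.data[None, :, None, None, None]
    k = w.shape[2]

    def backward(g):
        g = np.ascontiguousarray(g)
        dw = _conv_weight_grad(x.data, g, k) if w.requires_grad else None
        dx = None
        if x.requires_grad or x._parents:
            # data gradient = same-padded conv of g with flipped kernels
            w_flip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            dx = _conv_forward(g, w_flip)
        db = g.sum(axis=(0, 2, 3, 4)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents=parents, backward=backward)


def maxpool2(x):
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    xr = (
        x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(N, C, D // 2, H // 2, W // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(N, C, D, H, W)
        )
        return (gx,)

    return Tensor(out, parents=(x,), backward=backward)


def upsample2(x):
    """Nearest-neighbour 2x upsampling along all three spatial axes."""
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    N, C, D, H, W = x.shape

    def backward(g):
        return (g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7)),)

    return Tensor(out, parents=(x,), backward=backward)
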