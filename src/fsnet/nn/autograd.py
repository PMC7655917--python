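"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it in a dynamic graph; :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients.  The operation set is exactly
what an encoder–decoder segmentation network needs: broadcast arithmetic,
convolution (stride 1), non-overlapping transposed convolution, 2x2 max
pooling, global pooling, batch normalisation (in :mod:`fsnet.nn.modules`),
concatenation, pointwise nonlinearities and reductions.

Everything runs in whatever float dtype the inputs carry; float32 is the
training default, float64 is used where tests compare against references.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (must be scalar if grad is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data + other.data, (self, other))
        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data * other.data, (self, other))
        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data / other.data, (self, other))
        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1 - s))
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clamp(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = _make(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    t = Tensor(data)
    t._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return t


# --------------------------------------------------------------------------
# structural ops
# --------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])
    out._backward = bw
    return out


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes symmetrically."""
    if pad == 0:
        return x
    p = ((0, 0),) * (x.ndim - 2) + ((pad, pad), (pad, pad))
    out = _make(np.pad(x.data, p), (x,))
    sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
    out._backward = lambda g: x._accumulate(g[sl])
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 cross-correlation: x (N,C,H,W), w (O,C,kh,kw) -> (N,O,H',W').

    ``H' = H + 2*padding - kh + 1``; even kernels with symmetric padding are
    allowed (the dual 2x2 encoder relies on out = in + 2p - 1).
    """
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    kh, kw = w.data.shape[2:]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H',W',kh,kw
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # N,H',W',O
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    out = _make(out_data, (x, w) if b is None else (x, w, b))

    def bw(g):
        # weight gradient
        if w.requires_grad or w._parents:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # O,C,kh,kw
            w._accumulate(gw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            # full correlation of g with flipped kernel, channels swapped
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            win_g = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # N,O,H+2p,W+2p,kh,kw
            wf = w.data[:, :, ::-1, ::-1]
            gx = np.tensordot(win_g, wf, axes=([1, 4, 5], [0, 2, 3]))  # N,H+2p,W+2p,C
            gx = gx.transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(np.ascontiguousarray(gx))
    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping tiles).

    x (N,C,H,W), w (C,O,k,k) -> (N,O,H*k,W*k).  This is the 2x up-sampling
    operator of the decoder; kernel==stride keeps the scatter overlap-free so
    the op is a tensordot plus a reshape.
    """
    k = w.data.shape[2]
    if w.data.shape[3] != k or stride != k:
        raise ValueError("conv_transpose2d requires square kernel == stride")
    n, c, h, wd = x.data.shape
    o = w.data.shape[1]
    y = np.tensordot(x.data, w.data, axes=([1], [0]))  # N,H,W,O,k,k
    out_data = np.ascontiguousarray(
        y.transpose(0, 3, 1, 4, 2, 5).reshape(n, o, h * k, wd * k))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    out = _make(out_data, (x, w) if b is None else (x, w, b))

    def bw(g):
        gt = g.reshape(n, o, h, k, wd, k).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,O,k,k
        if w.requires_grad or w._parents:
            gw = np.tensordot(x.data, gt, axes=([0, 2, 3], [0, 1, 2]))  # C,O,k,k
            w._accumulate(gw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gx = np.tensordot(gt, w.data, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,C
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
    out._backward = bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (spatial size must divide k)."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial size ({h},{w}) not divisible by pool {k}")
    r = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]
    # break ties toward the first maximum, as framework pooling does
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
    out = _make(out_data, (x,))

    def bw(g):
        gx = mask * g[:, :, :, None, :, None]
        x._accumulate(gx.reshape(n, c, h, w))
    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) mean over the spatial grid."""
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) max over the spatial grid."""
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2).reshape(n, c, 1, 1)
    out = _make(out_data, (x,))

    def bw(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[:, :, None], g.reshape(n, c, 1), axis=2)
        x._accumulate(gx.reshape(n, c, h, w))
    out._backward = bw
    return out
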