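"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's neural models need: dense
and convolutional linear maps, pooling, pointwise nonlinearities,
reductions, concatenation/slicing, and numerically stable classification
losses.  Gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d",
           "bce_with_logits", "log_softmax", "smooth_l1"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data + other.data, _parents=(self, other),
                      _backward=lambda g: (_unbroadcast(g, self.data.shape),
                                           _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,),
                      _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data, _parents=(self, other),
            _backward=lambda g: (_unbroadcast(g * other.data, self.data.shape),
                                 _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data @ other.data, _parents=(self, other),
                      _backward=lambda g: (g @ other.data.T,
                                           self.data.T @ g))

    def __getitem__(self, idx):
        def bw(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _backward=lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(*axes), _parents=(self,),
                      _backward=lambda g: (g.transpose(*inv),))

    # -- pointwise ---------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,),
                      _backward=lambda g: (g * mask,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(out, _parents=(self,),
                      _backward=lambda g: (g * out * (1 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,),
                      _backward=lambda g: (g * (1 - out * out),))

    def exp(self):
        out = np.exp(np.clip(self.data, -60, 60))
        return Tensor(out, _parents=(self,),
                      _backward=lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.data), _parents=(self,),
                      _backward=lambda g: (g / self.data,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = (self.data.size if axis is None
             else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) / n


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis),
                  _parents=tuple(tensors), _backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """2-D cross-correlation, stride 1.  x: (N,C,H,W), w: (F,C,k,k)."""
    from numpy.lib.stride_tricks import sliding_window_view

    N, C, H, W = x.data.shape
    F, _, k, _ = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = H + 2 * pad - k + 1
    Wo = W + 2 * pad - k + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))       # N,C,Ho,Wo,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
    wmat = w.data.reshape(F, -1)
    out = (cols @ wmat.T + b.data).reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, F)
        gw = (g2.T @ cols).reshape(w.data.shape)
        gb = g2.sum(axis=0)
        gcols = (g2 @ wmat).reshape(N, Ho, Wo, C, k, k)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + Ho, j:j + Wo] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        gx = gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp
        return (gx, gw, gb)

    return Tensor(out, _parents=(x, w, b), _backward=bw)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; H and W must divide by ``size``."""
    N, C, H, W = x.data.shape
    Ho, Wo = H // size, W // size
    r = x.data.reshape(N, C, Ho, size, Wo, size)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, size * size)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(N, C, Ho, Wo, size, size) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return (gx,)

    return Tensor(out, _parents=(x,), _backward=bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights=None) -> Tensor:
    """Elementwise binary cross-entropy from logits (stable form).

    Returns a tensor shaped like ``logits``; combine with mean()/sum().
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    out = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        wts = np.asarray(weights, dtype=np.float64)
        out = out * wts

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        grad = (p - t)
        if weights is not None:
            grad = grad * wts
        return (g * grad,)

    return Tensor(out, _parents=(logits,), _backward=bw)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    z = logits.data
    m = z.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(z - m).sum(axis=axis, keepdims=True))
    out = z - lse

    def bw(g):
        p = np.exp(out)
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, _parents=(logits,), _backward=bw)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Elementwise Huber / smooth-L1 loss."""
    d = pred.data - np.asarray(target, dtype=np.float64)
    absd = np.abs(d)
    out = np.where(absd < beta, 0.5 * d * d / beta, absd - 0.5 * beta)

    def bw(g):
        return (g * np.where(absd < beta, d / beta, np.sign(d)),)

    return Tensor(out, _parents=(pred,), _backward=bw)
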