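"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the package's models need are provided: broadcast
add/mul, (batched) matmul, reshape/transpose, ReLU, last-axis softmax,
layer normalization, mean/sum reductions, 2-D convolution (im2col) and a
fused soft-target cross-entropy.  Everything is single-threaded NumPy and
fully deterministic given identical inputs, which the pipeline's
determinism contract relies on.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- graph mechanics -------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # ---- elementwise -----------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    def __neg__(self):
        return self * Tensor(np.asarray(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    # ---- linear algebra --------------------------------------------------

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            g = out.grad
            if self.requires_grad or self._prev:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._prev:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # ---- shape -----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw():
            self._accum(out.grad.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def _bw():
            self._accum(out.grad.transpose(*inv))

        out._backward = _bw
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.asarray(1.0 / n))

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bw():
            self._accum(out.grad * (self.data > 0))

        out._backward = _bw
        return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw():
        g = out.grad
        dot = (g * y).sum(axis=-1, keepdims=True)
        x._accum(y * (g - dot))

    out._backward = _bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, True, (x, gamma, beta))

    def _bw():
        g = out.grad
        lead = tuple(range(g.ndim - 1))
        gamma._accum((g * xhat).sum(axis=lead))
        beta._accum(g.sum(axis=lead))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        x._accum(inv * (dxhat - m1 - xhat * m2))

    out._backward = _bw
    return out


def cross_entropy_soft(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of logits (N,K) against soft target rows (N,K)."""
    t = np.asarray(targets, dtype=_DTYPE)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsum
    n = logits.data.shape[0]
    out = Tensor(-(t * logp).sum() / n, True, (logits,))

    def _bw():
        p = np.exp(logp)
        logits._accum(out.grad * (p - t) / n)

    out._backward = _bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad or t._prev for t in tensors), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad or t._prev:
                t._accum(g)

    out._backward = _bw
    return out


def take(x: Tensor, index: int, axis: int = 1) -> Tensor:
    """Select one index along an axis (e.g. the class/scale token output)."""
    out = Tensor(np.take(x.data, index, axis=axis), x.requires_grad, (x,))

    def _bw():
        g = np.zeros_like(x.data)
        sl = [slice(None)] * x.data.ndim
        sl[axis] = index
        g[tuple(sl)] = out.grad
        x._accum(g)

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, channels-last: x (B,H,W,Cin), w (k,k,Cin,Cout)."""
    k = w.data.shape[0]
    s = stride
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    B, H, W, C = xp.shape
    Ho = (H - k) // s + 1
    Wo = (W - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::s, ::s]                       # (B,Ho,Wo,C,k,k)
    cols = win.transpose(0, 1, 2, 4, 5, 3)       # (B,Ho,Wo,k,k,C)
    cols2 = cols.reshape(B * Ho * Wo, k * k * C)
    wf = w.data.reshape(k * k * C, -1)
    y = cols2 @ wf + b.data
    out = Tensor(y.reshape(B, Ho, Wo, -1), True, (x, w, b))

    def _bw():
        g = out.grad.reshape(B * Ho * Wo, -1)
        w._accum((cols2.T @ g).reshape(w.data.shape))
        b._accum(g.sum(axis=0))
        if x.requires_grad or x._prev:
            dcols = (g @ wf.T).reshape(B, Ho, Wo, k, k, C)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += dcols[:, :, :, i, j, :]
            if pad:
                dxp = dxp[:, pad:-pad, pad:-pad, :]
            x._accum(dxp)

    out._backward = _bw
    return out
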