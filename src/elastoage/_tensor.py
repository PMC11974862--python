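"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's models need: broadcasted
arithmetic, matmul, exp/log/pow, relu, axis reductions, reshape/transpose,
3D convolution (via im2col) and row-wise L2 normalisation. Gradients are
accumulated by a topological-order backward pass, the same scheme used by
every tape-based framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # ---- helpers -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # ---- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sqrt(self):
        return self**0.5

    # ---- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def backward(g):
            return (g.reshape(self.data.shape),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def l2_normalize(self, eps: float = 1e-12):
        """Row-wise unit-norm projection (last axis)."""
        norm = ((self**2.0).sum(axis=-1, keepdims=True) + eps).sqrt()
        return self / norm

    # ---- autodiff driver ------------------------------------------------
    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._prev, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else g


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution, NCDHW layout, cubic kernel.

    x: (N, Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    Implemented as im2col + matmul; the backward pass scatters column
    gradients back per kernel offset (k^3 vectorised adds).
    """
    N, Cin, D, H, W = x.data.shape
    Cout, Cin_w, k, _, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin} vs kernel {Cin_w}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    Do = (D + 2 * p - k) // s + 1
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]  # (N, Cin, Do, Ho, Wo, k, k, k)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N * Do * Ho * Wo, Cin * k**3)
    wmat = w.data.reshape(Cout, Cin * k**3).T
    out_data = cols @ wmat
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(N, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, Cout)
        gw = (cols.T @ gmat).T.reshape(w.data.shape)
        gcols = (gmat @ wmat.T).reshape(N, Do, Ho, Wo, Cin, k, k, k)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    gxp[:, :, a : a + Do * s : s, bb : bb + Ho * s : s, c : c + Wo * s : s] += (
                        gcols[:, :, :, :, :, a, bb, c].transpose(0, 4, 1, 2, 3)
                    )
        gx = gxp[:, :, p : p + D, p : p + H, p : p + W] if p else gxp
        grads = [gx, gw]
        if b is not None:
            grads.append(gmat.sum(axis=0))
        return tuple(grads)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in prev)
    if out.requires_grad:
        out._prev = prev
        out._backward = backward
    return out


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
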