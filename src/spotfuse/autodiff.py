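"""Minimal tape-based reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (a few thousand spots, latent widths of
tens), so a compact float64 engine is both fast enough and easier to make
bit-reproducible than a heavyweight framework.  Only the operations the models
need are provided: broadcasting arithmetic, matmul, the usual activations,
reductions, indexing/concatenation, log-gamma (for negative-binomial
likelihoods) and a grouped 2-D convolution.

Gradients propagate through a topologically sorted tape; broadcasting is
undone by summing gradients over the broadcast axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- construction helper ---------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        needs = any(p.requires_grad or p._prev for p in parents)
        if needs:
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def lgamma(self):
        def bwd(g):
            self._accumulate(g * digamma(self.data))

        return Tensor._make(gammaln(self.data), (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def softplus(self):
        # numerically stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * s)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bwd(g):
            self._accumulate(g * factor)

        return Tensor._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        ex = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(mask, self.data, ex)

        def bwd(g):
            self._accumulate(g * np.where(mask, 1.0, ex + alpha))

        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - t**2))

        return Tensor._make(t, (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bwd(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- softmax family -----------------------------------------------------
    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def bwd(g):
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), bwd)

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N,C,Hp,Wp) -> (N, C*kh*kw, oh*ow) patch matrix."""
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    n, c, oh, ow = v.shape[:4]
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0, groups=1):
    """Grouped 2-D convolution; x (N,C,H,W), w (O, C//groups, kh, kw)."""
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    n, c, h, wd = x.data.shape
    o, cg, kh, kw = w.data.shape
    assert c % groups == 0 and o % groups == 0 and cg == c // groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    og = o // groups
    outs, cols_g = [], []
    for gi in range(groups):
        xg = xp[:, gi * cg : (gi + 1) * cg]
        cols, oh, ow = _im2col(xg, kh, kw, sh, sw)
        cols_g.append(cols)
        wm = w.data[gi * og : (gi + 1) * og].reshape(og, -1)
        outs.append(np.einsum("ok,nkl->nol", wm, cols))
    out_data = np.concatenate(outs, axis=1).reshape(n, o, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)

    def bwd(g):
        gmat = g.reshape(n, o, oh * ow)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for gi in range(groups):
            gg = gmat[:, gi * og : (gi + 1) * og]
            wm = w.data[gi * og : (gi + 1) * og].reshape(og, -1)
            dw[gi * og : (gi + 1) * og] = np.einsum(
                "nol,nkl->ok", gg, cols_g[gi]
            ).reshape(og, cg, kh, kw)
            dcols = np.einsum("ok,nol->nkl", wm, gg)
            dcols = dcols.reshape(n, cg, kh, kw, oh, ow)
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :,
                        gi * cg : (gi + 1) * cg,
                        i : i + oh * sh : sh,
                        j : j + ow * sw : sw,
                    ] += dcols[:, :, i, j]
        x._accumulate(dxp[:, :, ph : ph + h, pw : pw + wd])
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bwd)


class Adam:
    """Adam optimizer over a fixed parameter list (deterministic update order)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
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
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
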