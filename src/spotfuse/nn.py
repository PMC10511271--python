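"""Small neural-network building blocks on top of :mod:`spotfuse.autodiff`.

Layers hold their parameters as :class:`~spotfuse.autodiff.Tensor` leaves and
expose ``params()`` for the optimizer.  Weight initialization is driven by an
explicit :class:`numpy.random.Generator` so every model in the package is a
pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = (fan_in, fan_out) if shape is None else shape
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    def params(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        out.extend(u.params())
                    elif isinstance(u, Tensor) and u.requires_grad:
                        out.append(u)
        return out


class Linear(Module):
    def __init__(self, rng, n_in, n_out, bias=True):
        self.w = glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, kernel, stride=1, padding=0, groups=1):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        fan_in = c_in // groups * kh * kw
        self.w = glorot(rng, fan_in, c_out, shape=(c_out, c_in // groups, kh, kw))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding, self.groups)


class BatchNorm1d(Module):
    """Batch normalization over axis 0 of a (batch, features) tensor."""

    def __init__(self, n_feat, eps=1e-5):
        self.gamma = Tensor(np.ones(n_feat), requires_grad=True)
        self.beta = Tensor(np.zeros(n_feat), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
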