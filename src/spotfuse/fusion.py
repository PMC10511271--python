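"""Global attention fusion of the per-view embeddings.

The per-view embeddings are linearly projected to a common width W and
stacked into a (C, H, W) tensor with C = views as channels and H = spots.
Channel attention gates every position with a sigmoid 2-layer MLP over the
channel axis (reduction ratio gamma); spatial attention gates with two
convolutions over the (H, W) plane (channel-reducing (k, 1) then
channel-restoring (1, k)).  The fused embedding is the channel sum
R = F3[1] + ... + F3[C], trained with a weak-supervision cross-entropy.
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import Adam, Tensor, stack
from .config import RunConfig
from .nn import Conv2d, Linear, Module

log = logging.getLogger("spotfuse")


class ChannelAttention(Module):
    """Per-position sigmoid MLP gate over the channel (view) axis."""

    def __init__(self, rng, n_channels, reduction):
        if reduction <= 0:
            raise ValueError("reduction ratio must be > 0")
        hidden = max(1, n_channels // reduction)
        self.l1 = Linear(rng, n_channels, hidden)
        self.l2 = Linear(rng, hidden, n_channels)

    def gate(self, f1: Tensor) -> Tensor:
        c, h, w = f1.shape
        perm = f1.transpose(1, 2, 0).reshape(h * w, c)
        g = self.l2(self.l1(perm).relu()).sigmoid()
        return g.reshape(h, w, c).transpose(2, 0, 1)

    def __call__(self, f1: Tensor) -> Tensor:
        return self.gate(f1) * f1


class SpatialAttention(Module):
    """Sigmoid gate from two convolutions over the (spots, latent) plane."""

    def __init__(self, rng, n_channels, reduction, kernel=7):
        hidden = max(1, n_channels // reduction)
        self.kernel = kernel
        self.conv1 = Conv2d(rng, n_channels, hidden, (kernel, 1), padding=(kernel // 2, 0))
        self.conv2 = Conv2d(rng, hidden, n_channels, (1, kernel), padding=(0, kernel // 2))

    def gate(self, f2: Tensor) -> Tensor:
        c, h, w = f2.shape
        k = self.kernel
        if k > h or k > w:
            log.warning("spatial-attention kernel %d exceeds plane (%d, %d)", k, h, w)
        x = f2.reshape(1, c, h, w)
        g = self.conv2(self.conv1(x).relu()).sigmoid()
        return g.reshape(c, h, w)

    def __call__(self, f2: Tensor) -> Tensor:
        return self.gate(f2) * f2


def channel_attention(f1: np.ndarray, gamma: int = 4, seed: int = 0) -> np.ndarray:
    """Functional channel attention (untrained weights): F2 = Mc(F1) * F1."""
    f1 = np.asarray(f1, dtype=float)
    mod = ChannelAttention(np.random.default_rng(seed), f1.shape[0], gamma)
    return mod(Tensor(f1)).numpy()


def spatial_attention(f2: np.ndarray, gamma: int = 4, kernel: int = 7, seed: int = 0):
    """Functional spatial attention (untrained weights): F3 = Ms(F2) * F2."""
    f2 = np.asarray(f2, dtype=float)
    mod = SpatialAttention(np.random.default_rng(seed), f2.shape[0], gamma, kernel)
    return mod(Tensor(f2)).numpy()


class _GamModel(Module):
    def __init__(self, rng, view_dims, width, reduction, kernel, n_classes):
        c = len(view_dims)
        self.projs = [Linear(rng, d, width) for d in view_dims]
        self.chan = ChannelAttention(rng, c, reduction)
        self.spat = SpatialAttention(rng, c, reduction, kernel)
        self.head = Linear(rng, width, n_classes) if n_classes else None

    def fuse(self, views: list[Tensor], force_gates: bool = False) -> Tensor:
        f1 = stack([p(v) for p, v in zip(self.projs, views)], axis=0)
        if force_gates:
            return f1.sum(axis=0)
        f3 = self.spat(self.chan(f1))
        return f3.sum(axis=0)


def fuse_views(
    view_embeddings: list[np.ndarray],
    labels: np.ndarray | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    force_gates: bool = False,
):
    """Fuse >= 2 per-view embeddings into one (spots x W) representation R.

    All views must cover the same spots in the same order.  With integer
    `labels` (-1 = unlabeled) the attention weights and a linear softmax head
    are trained by cross-entropy on the labeled spots; without labels the
    (deterministically initialized) attention is applied untrained.
    Returns (R, losses).
    """
    cfg = config or RunConfig()
    if len(view_embeddings) < 2:
        raise ValueError("fusion needs at least 2 views")
    n = view_embeddings[0].shape[0]
    for v in view_embeddings[1:]:
        if v.shape[0] != n:
            raise ValueError(
                f"views cover different spot sets: {[e.shape[0] for e in view_embeddings]}"
            )
    std_views = []
    for v in view_embeddings:
        v = np.asarray(v, dtype=float)
        std_views.append(Tensor((v - v.mean(axis=0)) / (v.std(axis=0) + 1e-8)))
    rng = np.random.default_rng(seed)
    labels = None if labels is None else np.asarray(labels, dtype=int)
    lab_idx = (
        np.nonzero(labels >= 0)[0] if labels is not None else np.array([], dtype=int)
    )
    n_classes = int(labels.max()) + 1 if lab_idx.size else 0
    model = _GamModel(
        rng, [v.shape[1] for v in std_views], cfg.gam_width,
        cfg.gam_reduction, cfg.gam_kernel, n_classes,
    )
    losses = []
    n_epochs = cfg.gam_epochs if epochs is None else epochs
    if n_classes:
        opt = Adam(model.params(), lr=cfg.gam_lr)
        for epoch in range(n_epochs):
            r = model.fuse(std_views, force_gates)
            logp = model.head(r).log_softmax(axis=1)
            loss = -(logp[lab_idx, labels[lab_idx]].mean())
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"GAM diverged (NaN loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if losses:
            log.info("GAM: %d epochs, loss %.4f -> %.4f", len(losses), losses[0], losses[-1])
    r = model.fuse(std_views, force_gates).numpy()
    return r, losses
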