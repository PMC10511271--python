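"""Per-spot visual features from histology patches by contrastive pretraining.

The scheme follows the three-stage SimCLRv2 recipe at desk scale: (1)
task-agnostic pretraining of a small convolutional encoder with the NT-Xent
loss on two stochastic augmentations (crop-resize, color jitter, Gaussian
blur) of every patch; (2) optional task-specific fine-tuning from the middle
of the projection head using labeled spots; (3) optional distillation of the
fine-tuned teacher into a smaller student with a softened cross-entropy.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import gaussian as _gaussian_blur
from skimage.transform import resize as _resize

from .autodiff import Adam, Tensor, concat
from .config import RunConfig
from .nn import Conv2d, Linear, Module

log = logging.getLogger("spotfuse")


# -- augmentation -------------------------------------------------------------
def _augment_once(img: np.ndarray, rng) -> np.ndarray:
    """crop-resize -> color jitter -> Gaussian blur on a [0,1] float image."""
    px = img.shape[0]
    scale = rng.uniform(0.5, 1.0)
    crop = max(4, int(round(px * scale)))
    r0 = rng.integers(0, px - crop + 1)
    c0 = rng.integers(0, px - crop + 1)
    out = img[r0 : r0 + crop, c0 : c0 + crop]
    out = _resize(out, (px, px, 3), order=1, mode="reflect", anti_aliasing=False)
    brightness = rng.uniform(-0.2, 0.2)
    contrast = rng.uniform(0.8, 1.2)
    out = np.clip((out - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0)
    sigma = rng.uniform(0.0, 1.0)
    if sigma > 1e-3:
        out = _gaussian_blur(out, sigma=sigma, channel_axis=2)
    return np.clip(out, 0.0, 1.0)


def augment_patch(patch: np.ndarray, seed: int = 0):
    """Two independent augmented views of an RGB patch (uint8 or [0,1] float)."""
    patch = np.asarray(patch)
    if patch.shape[0] < 4 or patch.shape[1] < 4:
        raise ValueError("patch smaller than the minimum crop size (4 px)")
    img = patch.astype(float) / 255.0 if patch.dtype == np.uint8 else patch.astype(float)
    rng = np.random.default_rng(seed)
    return _augment_once(img, rng), _augment_once(img, rng)


# -- losses -------------------------------------------------------------------
def nt_xent_loss(z, tau: float = 0.5) -> float:
    """Normalized temperature-scaled cross-entropy on (2N, d) paired rows.

    Rows (2k, 2k+1) are the two views of source k.  Each ordered pair
    contributes -log softmax of the positive cosine/tau over its 2N-1
    non-self similarities; the loss is the mean over all 2N ordered pairs.
    """
    z = np.asarray(z, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm row in projection matrix")
    m = z.shape[0]
    if m % 2:
        raise ValueError("z must contain an even number of rows (view pairs)")
    sim = (z / norms[:, None]) @ (z / norms[:, None]).T / tau
    np.fill_diagonal(sim, -np.inf)
    partner = np.arange(m) ^ 1
    logits = sim - sim.max(axis=1, keepdims=True)
    logprob = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return float(-logprob[np.arange(m), partner].mean())


def _nt_xent_t(z: Tensor, tau: float) -> Tensor:
    """Differentiable NT-Xent; masks the diagonal with a large negative shift."""
    m = z.shape[0]
    norms = ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    zn = z / norms
    sim = (zn @ zn.T) * (1.0 / tau)
    mask = Tensor(np.eye(m) * 1e9)
    sim = sim - mask
    logp = sim.log_softmax(axis=1)
    partner = np.arange(m) ^ 1
    return -(logp[np.arange(m), partner].mean())


def distill_loss(teacher_logits, student_logits, tau: float = 1.0):
    """Softened cross-entropy  -mean_i sum_y P_T(y|x_i) log P_S(y|x_i).

    Equals the teacher entropy when the distributions coincide; the excess
    over the teacher entropy is KL(P_T || P_S) >= 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(teacher_logits, dtype=float) / tau
    s = np.asarray(student_logits, dtype=float) / tau
    if t.shape != s.shape:
        raise ValueError("teacher and student logits must have the same shape")
    t = t - t.max(axis=1, keepdims=True)
    s = s - s.max(axis=1, keepdims=True)
    pt = np.exp(t) / np.exp(t).sum(axis=1, keepdims=True)
    logps = s - np.log(np.exp(s).sum(axis=1, keepdims=True))
    return float(-(pt * logps).sum(axis=1).mean())


# -- model --------------------------------------------------------------------
class _ConvEncoder(Module):
    """Four stride-2 conv blocks with ELU, then global average pooling."""

    def __init__(self, rng, d_out, widths=(8, 16, 32, 64)):
        chans = (3,) + tuple(widths)
        self.blocks = [
            Conv2d(rng, chans[i], chans[i + 1], 3, stride=2, padding=1)
            for i in range(len(widths))
        ]
        self.proj = Linear(rng, widths[-1], d_out) if d_out != widths[-1] else None

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk(h).elu()
        h = h.mean(axis=(2, 3))
        return self.proj(h) if self.proj else h


class _Projection(Module):
    """Three-layer projection head; layer 1 output is the fine-tuning input."""

    def __init__(self, rng, d_in, d_mid, d_out):
        self.l1 = Linear(rng, d_in, d_mid)
        self.l2 = Linear(rng, d_mid, d_mid)
        self.l3 = Linear(rng, d_mid, d_out)

    def mid(self, h: Tensor) -> Tensor:
        return self.l1(h).relu()

    def __call__(self, h: Tensor) -> Tensor:
        return self.l3(self.l2(self.mid(h)).relu())


def _to_nchw(patches: np.ndarray) -> np.ndarray:
    x = patches.astype(float)
    if x.max() > 1.5:
        x = x / 255.0
    return np.transpose(x, (0, 3, 1, 2)) - 0.5


def train_contrastive(
    patches: np.ndarray,
    config: RunConfig | None = None,
    seed: int = 0,
    labels: np.ndarray | None = None,
):
    """Learn per-spot visual features v from image patches.

    Pretrains encoder + projection with NT-Xent; when integer `labels`
    (-1 = unlabeled) are given, fine-tunes a classifier from the first
    projection layer and returns the mid-projection output as v, otherwise
    the encoder output.  Returns (v, losses).
    """
    cfg = config or RunConfig()
    patches = np.asarray(patches)
    n = patches.shape[0]
    if n < 32:
        raise ValueError("need at least 32 patches for contrastive training")
    batch = cfg.simclr_batch
    if batch > n:
        log.warning("batch size %d clipped to %d patches", batch, n)
        batch = n
    rng = np.random.default_rng(seed)
    d_v = cfg.visual_dim
    enc = _ConvEncoder(rng, d_v)
    proj = _Projection(rng, d_v, d_v, 32)
    opt = Adam(enc.params() + proj.params(), lr=cfg.simclr_lr)
    losses = []
    for epoch in range(cfg.simclr_epochs):
        order = rng.permutation(n)
        ep_loss = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            if len(idx) < 2:
                continue
            views = []
            for i in idx:
                a, b = augment_patch(patches[i], seed=int(rng.integers(2**31)))
                views.extend([a, b])
            x = Tensor(_to_nchw(np.stack(views)))
            z = proj(enc(x))
            loss = _nt_xent_t(z, cfg.simclr_tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss.append(loss.item())
        losses.append(float(np.mean(ep_loss)))
    x_all = Tensor(_to_nchw(patches))
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        lab_idx = np.nonzero(labels >= 0)[0]
        if lab_idx.size:
            k = int(labels.max()) + 1
            head = Linear(rng, d_v, k)
            opt2 = Adam(enc.params() + proj.l1.params() + head.params(), lr=cfg.simclr_lr)
            for _ in range(max(5, cfg.simclr_epochs // 2)):
                h = proj.mid(enc(Tensor(_to_nchw(patches[lab_idx]))))
                logp = head(h).log_softmax(axis=1)
                loss = -(logp[np.arange(lab_idx.size), labels[lab_idx]].mean())
                opt2.zero_grad()
                loss.backward()
                opt2.step()
            v = proj.mid(enc(x_all)).numpy()
            return v, losses
    return enc(x_all).numpy(), losses


def train_distilled_student(
    patches, teacher_logits, config=None, seed=0, tau=1.0, widths=(8, 16)
):
    """Distill teacher class logits into a smaller (2-block) student encoder."""
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    k = np.asarray(teacher_logits).shape[1]
    student = _ConvEncoder(rng, k, widths=widths)
    opt = Adam(student.params(), lr=cfg.simclr_lr)
    t = np.asarray(teacher_logits, dtype=float) / tau
    t = t - t.max(axis=1, keepdims=True)
    pt = Tensor(np.exp(t) / np.exp(t).sum(axis=1, keepdims=True))
    x = Tensor(_to_nchw(np.asarray(patches)))
    losses = []
    for _ in range(cfg.simclr_epochs):
        logits = student(x) * (1.0 / tau)
        loss = -((pt * logits.log_softmax(axis=1)).sum(axis=1).mean())
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return student, losses
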