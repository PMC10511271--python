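"""Expression feature extraction: HVG selection and a negative-binomial autoencoder.

The autoencoder follows the fixed frame [G, hidden, latent, hidden, G]
(published as [2000, 1000, 50, 1000, 2000]): a fully connected encoder with
batch normalization, ReLU and dropout maps library-normalized log counts to a
latent z; two decoder heads emit the NB mean (softmax proportions scaled by
the spot's library size, switchable to softplus) and dispersion (softplus).
Training minimizes the mean NB negative log-likelihood of the raw counts with
Adam.  The latent matrix z is the expression feature matrix X0 used as node
features by every view graph.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln

from .autodiff import Adam, Tensor
from .config import RunConfig
from .nn import BatchNorm1d, Linear, Module, dropout

log = logging.getLogger("spotfuse")


def select_hvg(counts: np.ndarray, n_top: int, gene_ids=None):
    """Keep the n_top most variable genes of a spots x genes count matrix.

    The variability score is the variance of log1p library-normalized
    counts — the log-scale dispersion proxy used by standard HVG selection,
    which is nearly flat in expression level for overdispersed counts, so
    genes with structured (e.g. spatial) signal rise to the top.  Ties break
    deterministically by gene id (original column order when ids are
    absent); constant genes score zero and rank last.  Returns the reduced
    matrix and the kept column indices in original order.
    """
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    if n_top > g:
        raise ValueError(f"n_top={n_top} exceeds {g} genes")
    lib = counts.sum(axis=1)
    lib = np.where(lib == 0, 1.0, lib)
    logn = np.log1p(counts / lib[:, None] * np.median(lib))
    score = logn.var(axis=0)
    ids = [str(i) for i in (gene_ids if gene_ids is not None else range(g))]
    order = sorted(range(g), key=lambda j: (-score[j], ids[j]))
    keep = np.sort(np.array(order[:n_top]))
    return counts[:, keep], keep


def nb_negative_loglik(x, u, theta) -> float:
    """Total NB negative log-likelihood -sum log NB(x; u, theta).

    Mean/dispersion parameterization: NB(x) = Gamma(x+theta) / (Gamma(theta)
    Gamma(x+1)) (u/(u+theta))^x (theta/(theta+u))^theta.
    """
    x = np.asarray(x, dtype=float)
    u = np.broadcast_to(np.asarray(u, dtype=float), x.shape)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), x.shape)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must be non-negative integers")
    if np.any(u <= 0) or np.any(theta <= 0):
        raise ValueError("u and theta must be positive")
    ll = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1)
        + theta * np.log(theta / (theta + u))
        + x * np.log(u / (theta + u))
    )
    return float(-ll.sum())


def _nb_nll_mean(x: Tensor, u: Tensor, theta: Tensor) -> Tensor:
    """Differentiable mean NB NLL (x is a constant tensor)."""
    ll = (
        (x + theta).lgamma()
        - theta.lgamma()
        - Tensor(gammaln(x.data + 1.0))
        + theta * ((theta / (theta + u)).log())
        + x * ((u / (theta + u)).log())
    )
    return -ll.mean()


class NbAutoencoder(Module):
    def __init__(self, rng, n_genes, hidden, latent, dropout_rate, mean_head):
        self.enc1 = Linear(rng, n_genes, hidden)
        self.enc_bn = BatchNorm1d(hidden)
        self.enc2 = Linear(rng, hidden, latent)
        self.dec1 = Linear(rng, latent, hidden)
        self.dec_bn = BatchNorm1d(hidden)
        self.dec_u = Linear(rng, hidden, n_genes)
        self.dec_theta = Linear(rng, hidden, n_genes)
        self.dropout_rate = dropout_rate
        self.mean_head = mean_head

    def encode(self, x: Tensor, rng=None, train=False) -> Tensor:
        h = self.enc_bn(self.enc1(x)).relu()
        if train:
            h = dropout(h, self.dropout_rate, rng, train)
        return self.enc2(h)

    def decode(self, z: Tensor, lib: np.ndarray):
        h = self.dec_bn(self.dec1(z)).relu()
        if self.mean_head == "softmax":
            u = self.dec_u(h).softmax(axis=1) * Tensor(lib[:, None])
        else:
            u = self.dec_u(h).softplus() + 1e-6
        theta = self.dec_theta(h).softplus() + 1e-4
        return u, theta


def train_expr_ae(counts_hvg: np.ndarray, config: RunConfig | None = None, seed: int = 0):
    """Train the NB autoencoder on a spots x genes count matrix; return X0.

    Returns (X0, losses) where X0 is the (spots x latent) latent matrix and
    losses the per-epoch mean NB NLL.  Full-batch training; deterministic
    given the seed.
    """
    cfg = config or RunConfig()
    counts = np.asarray(counts_hvg, dtype=float)
    n, g = counts.shape
    hidden = min(cfg.ae_hidden, max(64, 4 * g))  # cap width at desk scale
    latent = min(cfg.ae_latent, g)
    rng = np.random.default_rng(seed)
    model = NbAutoencoder(
        rng, g, hidden, latent, cfg.ae_dropout, cfg.ae_mean_head
    )
    total = counts.sum(axis=1)
    lib = np.where(total == 0, 1.0, total)
    xin = np.log1p(counts / lib[:, None] * lib.mean())
    xin_t = Tensor((xin - xin.mean(axis=0)) / (xin.std(axis=0) + 1e-8))
    x_t = Tensor(counts)
    opt = Adam(model.params(), lr=cfg.ae_lr, weight_decay=cfg.ae_weight_decay)
    losses = []
    for epoch in range(cfg.ae_epochs):
        z = model.encode(xin_t, rng=rng, train=True)
        u, theta = model.decode(z, lib)
        loss = _nb_nll_mean(x_t, u, theta)
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"NB autoencoder diverged (NaN loss) at epoch {epoch}, "
                f"lr={cfg.ae_lr}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    x0 = model.encode(xin_t, train=False).numpy()
    if losses:
        log.info("NB-AE: %d epochs, loss %.4f -> %.4f", len(losses), losses[0], losses[-1])
    return x0, losses
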