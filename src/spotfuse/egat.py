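"""Edge-feature-enhanced graph attention encoder (EGAT).

Each layer computes attention scores f_ij = exp(LeakyReLU(a^T [W x_i || W x_j])),
modulates them channel-wise by the previous layer's edge features,
doubly-stochastically normalizes every channel, aggregates W x over each
channel and concatenates; the attention tensor becomes the next layer's edge
features.  The doubly stochastic step is the closed form

    T_ij = A_ij / sum_k A_ik            (row normalization)
    E_ij = sum_k T_ik T_jk / sum_v T_vk

which is symmetric with unit row (hence column) sums.

Training minimizes binary cross-entropy between the graph adjacency and its
inner-product decoding sigmoid(R R^T), plus a weak-supervision cross-entropy
on labeled spots weighted by `egat_loss_weight` (published weight 8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat
from .config import RunConfig
from .graphs import ViewGraph
from .nn import Linear, Module, glorot

log = logging.getLogger("spotfuse")


# -- doubly stochastic normalization ----------------------------------------
def _ds_channel_t(a: Tensor, guard_row: np.ndarray, guard_col: np.ndarray) -> Tensor:
    """Differentiable DS normalization of one non-negative channel."""
    row = a.sum(axis=1, keepdims=True) + Tensor(guard_row)
    t = a / row
    col = t.sum(axis=0, keepdims=True) + Tensor(guard_col)
    return t @ (t / col).T


def _guards(a: np.ndarray):
    row = (a.sum(axis=1, keepdims=True) == 0).astype(float)
    t = a / (a.sum(axis=1, keepdims=True) + row)
    col = (t.sum(axis=0, keepdims=True) == 0).astype(float)
    return row, col


def ds_normalize(e_hat: np.ndarray) -> np.ndarray:
    """Doubly stochastic normalization of an (n, n, P) positive edge tensor.

    Entries off the graph support are zeros; every node must have at least
    one incident edge per channel (isolated rows raise).
    """
    e_hat = np.asarray(e_hat, dtype=float)
    single = e_hat.ndim == 2
    if single:
        e_hat = e_hat[:, :, None]
    if np.any(e_hat < 0):
        raise ValueError("edge features must be non-negative")
    out = np.empty_like(e_hat)
    for p in range(e_hat.shape[2]):
        a = e_hat[:, :, p]
        rows = a.sum(axis=1)
        if np.any(rows == 0):
            bad = np.nonzero(rows == 0)[0][:5]
            raise ValueError(f"isolated nodes (zero rows) in channel {p}: {bad}")
        t = a / rows[:, None]
        col = t.sum(axis=0)
        col = np.where(col == 0, 1.0, col)
        out[:, :, p] = t @ (t / col[None, :]).T
    return out[:, :, 0] if single else out


# -- layers ------------------------------------------------------------------
@dataclass
class EgatLayerParams:
    """Parameters of one EGAT layer: linear map W, attention vector a."""

    w: np.ndarray  # (F_in, F_out)
    a: np.ndarray  # (2 * F_out,)
    leaky_slope: float = 0.2


class _EgatLayer(Module):
    def __init__(self, rng, f_in, f_out, n_channels, slope):
        self.w = glorot(rng, f_in, f_out)
        self.a = Tensor(
            np.random.default_rng(rng.integers(2**31)).normal(
                0.0, 0.1, size=2 * f_out
            ),
            requires_grad=True,
        )
        self.slope = slope
        self.n_channels = n_channels

    def __call__(self, x: Tensor, e: Tensor):
        """x: (n, F_in); e: (n, n, P) non-negative, zeros off-support."""
        wx = x @ self.w
        f_out = self.w.data.shape[1]
        n = x.shape[0]
        u = wx @ self.a[:f_out].reshape(f_out, 1)
        v = wx @ self.a[f_out:].reshape(f_out, 1)
        scores = u.reshape(n, 1) + v.reshape(1, n)
        scores = scores.leaky_relu(self.slope)
        # subtracting the (detached) row max leaves the DS output unchanged
        # (per-row scale cancels in the row normalization) but avoids overflow
        shift = scores.data.max(axis=1, keepdims=True)
        f = (scores - Tensor(shift)).exp()
        outs, alphas = [], []
        for p in range(self.n_channels):
            ep = e[:, :, p]
            a_hat = f * ep
            gr, gc = _guards(a_hat.data)
            alpha = _ds_channel_t(a_hat, gr, gc)
            alphas.append(alpha)
            outs.append(alpha @ wx)
        x_next = concat(outs, axis=1).elu()
        from .autodiff import stack as t_stack

        e_next = t_stack(alphas, axis=2)
        return x_next, e_next

    def params_struct(self) -> EgatLayerParams:
        return EgatLayerParams(
            w=self.w.data.copy(), a=self.a.data.copy(), leaky_slope=self.slope
        )


def egat_layer(x_prev: np.ndarray, e_prev: np.ndarray, params: EgatLayerParams):
    """One EGAT layer as a pure function of numpy inputs (no training).

    x_prev: (n, F_in); e_prev: (n, n, P) non-negative with zeros off-support.
    Returns (x_next, e_next) with x_next (n, P * F_out) and e_next the
    attention tensor (doubly stochastic per channel).
    """
    x_prev = np.asarray(x_prev, dtype=float)
    e_prev = np.asarray(e_prev, dtype=float)
    if e_prev.ndim != 3:
        raise ValueError("e_prev must be (n, n, P)")
    rngless = _EgatLayer.__new__(_EgatLayer)
    rngless.w = Tensor(params.w)
    rngless.a = Tensor(params.a)
    rngless.slope = params.leaky_slope
    rngless.n_channels = e_prev.shape[2]
    x_t, e_t = rngless(Tensor(x_prev), Tensor(e_prev))
    return x_t.numpy(), e_t.numpy()


# -- decoding and loss --------------------------------------------------------
def decode_adjacency(r: np.ndarray) -> np.ndarray:
    """Inner-product decoder A' = sigmoid(R R^T)."""
    r = np.asarray(r, dtype=float)
    logits = r @ r.T
    return 1.0 / (1.0 + np.exp(-logits))


def egat_loss(a, a_prime, y=None, y_prime=None, labeled=None, weight=8.0):
    """(L, parts): mean BCE(A, A') over all n^2 pairs + weight * mean CE.

    `labeled` is an index/boolean selector of supervised spots; with no
    labels the classification part is 0 (unsupervised mode).
    """
    a = np.asarray(a, dtype=float)
    ap = np.clip(np.asarray(a_prime, dtype=float), 1e-7, 1 - 1e-7)
    l_recon = float(-np.mean(a * np.log(ap) + (1 - a) * np.log(1 - ap)))
    l_cls = 0.0
    idx = np.array([], dtype=int)
    if labeled is not None:
        sel = np.asarray(labeled)
        idx = np.nonzero(sel)[0] if sel.dtype == bool else sel.astype(int)
    if y is not None and y_prime is not None and idx.size:
        yp = np.clip(np.asarray(y_prime, dtype=float), 1e-12, None)
        ys = np.asarray(y)[idx]
        l_cls = float(-np.mean(np.log(yp[idx, ys])))
    else:
        log.warning("egat_loss: no labeled spots, classification term is 0")
    total = l_recon + weight * l_cls
    return total, {"recon": l_recon, "cls": l_cls}


class _EgatModel(Module):
    def __init__(self, rng, f_in, hidden, out, n_channels, n_classes, slope):
        self.layer1 = _EgatLayer(rng, f_in, hidden, n_channels, slope)
        self.layer2 = _EgatLayer(rng, n_channels * hidden, out, n_channels, slope)
        self.head = Linear(rng, n_channels * out, n_classes) if n_classes else None

    def forward(self, x: Tensor, e: Tensor):
        x1, e1 = self.layer1(x, e)
        x2, _ = self.layer2(x1, e1)
        return x2


def train_egat(
    view_graph: ViewGraph,
    labels: np.ndarray | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
):
    """Train a 2-layer EGAT on one view; return the spot embedding R_m.

    `labels` holds integer class codes with -1 for unlabeled spots; pass None
    for fully unsupervised training.  Returns (R, losses).
    """
    cfg = config or RunConfig()
    n_epochs = cfg.egat_epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    x = (view_graph.node_features - view_graph.node_features.mean(axis=0)) / (
        view_graph.node_features.std(axis=0) + 1e-8
    )
    e0 = view_graph.to_dense()
    adj = view_graph.adjacency()
    labels = None if labels is None else np.asarray(labels, dtype=int)
    labeled_idx = (
        np.nonzero(labels >= 0)[0] if labels is not None else np.array([], dtype=int)
    )
    n_classes = int(labels.max()) + 1 if labeled_idx.size else 0
    model = _EgatModel(
        rng, x.shape[1], cfg.egat_hidden, cfg.egat_out,
        view_graph.n_channels, n_classes, cfg.leaky_slope,
    )
    x_t, e_t = Tensor(x), Tensor(e0)
    adj_t = Tensor(adj)
    opt = Adam(model.params(), lr=cfg.egat_lr)
    losses = []
    n = view_graph.n_nodes
    for epoch in range(n_epochs):
        r = model.forward(x_t, e_t)
        logits = r @ r.T
        # BCE from logits: -[a * logsig(z) + (1-a) * logsig(-z)]
        l_recon = (
            (adj_t * (-logits).softplus() + (1 - adj_t) * logits.softplus()).sum()
            * (1.0 / (n * n))
        )
        loss = l_recon
        if n_classes:
            logp = model.head(r).log_softmax(axis=1)
            picked = logp[labeled_idx, labels[labeled_idx]]
            loss = loss + (-picked.mean()) * cfg.egat_loss_weight
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"EGAT diverged (NaN loss) at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    r = model.forward(x_t, e_t).numpy()
    if losses:
        log.info(
            "EGAT[%s]: %d epochs, loss %.4f -> %.4f",
            view_graph.view_name, len(losses), losses[0], losses[-1],
        )
    return r, losses
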