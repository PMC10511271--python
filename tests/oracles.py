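"""Loop-based reference implementations shared by the EGAT tests."""

import numpy as np


def oracle_ds(a):
    """Dense two-stage doubly stochastic normalization, written with loops."""
    n = a.shape[0]
    t = np.zeros_like(a)
    for i in range(n):
        t[i] = a[i] / a[i].sum()
    col = t.sum(axis=0)
    out = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(n):
                if col[k] > 0:
                    s += t[i, k] * t[j, k] / col[k]
            out[i, j] = s
    return out


def oracle_egat_layer(x, e, params):
    """Per-node, per-pair reference for one EGAT layer."""
    n = x.shape[0]
    p_ch = e.shape[2]
    w, a, slope = params.w, params.a, params.leaky_slope
    wx = x @ w
    f = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = np.concatenate([wx[i], wx[j]]) @ a
            f[i, j] = np.exp(s if s > 0 else slope * s)
    outs = []
    alphas = np.zeros((n, n, p_ch))
    for p in range(p_ch):
        alpha = oracle_ds(f * e[:, :, p])
        alphas[:, :, p] = alpha
        outs.append(alpha @ wx)
    h = np.concatenate(outs, axis=1)
    out = np.where(h > 0, h, np.exp(np.minimum(h, 0)) - 1.0)  # ELU
    return out, alphas


def random_graph_tensor(rng, n, p_ch):
    """Connected random support with positive channel features."""
    e = np.zeros((n, n, p_ch))
    for i in range(n - 1):
        v = rng.uniform(0.2, 1.5, size=p_ch)
        e[i, i + 1] = v
        e[i + 1, i] = v
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            v = rng.uniform(0.2, 1.5, size=p_ch)
            e[i, j] = v
            e[j, i] = v
    return e
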