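"""Construction of the three view graphs and their multidimensional edge features.

Views share one container (:class:`ViewGraph`): a symmetric k-nearest-neighbor
edge set under the view's natural metric, each edge carrying a P-channel
positive real feature vector.

* HSG (histological similarity): node features X0, kNN under cosine distance
  of the visual features v; edge features (cosine, exp(-L2), Pearson) of v.
* SLG (spatial location): kNN under Euclidean distance of the coordinates;
  edge features (planar dot / distance, distance <= lambda, |dy| <= mu) plus,
  in 3D, |dz| <= xi.
* GAG (gene association): node features are the autoencoded conditional
  degree matrix, kNN under cosine distance of the expression features w;
  edge features (cosine, exp(-L2), Pearson) of w.

The conditional degree matrix counts, per cell, how many partners each gene
is associated with once a hub "conditioning" gene is held fixed — a
cell-specific conditional-independence network thresholded at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, pearsonr


@dataclass
class ViewGraph:
    """Node features + symmetric edge list + P-channel positive edge features.

    `edges` stores both orientations of every undirected edge;
    `edge_features` is the strictly positive (shifted) tensor consumed by
    EGAT, `raw_edge_features` the pre-shift values.
    """

    view_name: str
    node_features: np.ndarray
    edges: np.ndarray  # (E, 2) int, both orientations
    edge_features: np.ndarray  # (E, P) strictly positive
    raw_edge_features: np.ndarray  # (E, P) pre-shift

    def __post_init__(self):
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if not np.all(np.isfinite(self.edge_features)) or np.any(
            self.edge_features <= 0
        ):
            raise ValueError("edge features must be finite and strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.edge_features.shape[1]

    def to_dense(self) -> np.ndarray:
        """(n, n, P) tensor with zeros off-support."""
        n, p = self.n_nodes, self.n_channels
        dense = np.zeros((n, n, p))
        dense[self.edges[:, 0], self.edges[:, 1]] = self.edge_features
        return dense

    def adjacency(self) -> np.ndarray:
        n = self.n_nodes
        a = np.zeros((n, n))
        a[self.edges[:, 0], self.edges[:, 1]] = 1.0
        return a

    def save(self, prefix):
        """Write `<prefix>_edges.tsv` (i, j, e1..eP, raw1..rawP) and
        `<prefix>_nodes.tsv`."""
        import pandas as pd

        p = self.n_channels
        cols = {"i": self.edges[:, 0], "j": self.edges[:, 1]}
        for c in range(p):
            cols[f"e{c + 1}"] = self.edge_features[:, c]
        for c in range(p):
            cols[f"raw{c + 1}"] = self.raw_edge_features[:, c]
        pd.DataFrame(cols).to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
        pd.DataFrame(self.node_features).to_csv(
            f"{prefix}_nodes.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, prefix, view_name):
        import pandas as pd

        ed = pd.read_csv(f"{prefix}_edges.tsv", sep="\t")
        nf = pd.read_csv(f"{prefix}_nodes.tsv", sep="\t").to_numpy()
        p = sum(c.startswith("e") and c[1:].isdigit() for c in ed.columns)
        return cls(
            view_name=view_name,
            node_features=nf,
            edges=ed[["i", "j"]].to_numpy(),
            edge_features=ed[[f"e{c + 1}" for c in range(p)]].to_numpy(),
            raw_edge_features=ed[[f"raw{c + 1}" for c in range(p)]].to_numpy(),
        )


# -- edge feature primitives ------------------------------------------------
def similarity_edge_features(a, b):
    """(cosine, exp(-||a-b||), Pearson) between two feature vectors.

    Pearson is defined as 0 when either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("vectors must have length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    e1 = float(a @ b / (na * nb))
    e2 = float(np.exp(-np.linalg.norm(a - b)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        e3 = 0.0
    else:
        e3 = float(pearsonr(a, b).statistic)
    return e1, e2, e3


def location_edge_features(s_i, s_j, lam, mu, xi=None, mu_rule="le"):
    """SLG edge features from two spot positions.

    e1 = planar dot product / planar distance; e2 = [distance <= lambda];
    e3 = [|dy| <= mu] (or > mu when mu_rule="gt"); with xi given, a fourth
    channel e4 = [|dz| <= xi].
    """
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    dxy = s_i[:2] - s_j[:2]
    dist = float(np.linalg.norm(dxy))
    if np.allclose(s_i, s_j):
        raise ValueError("coincident spots: e1 denominator is zero")
    e1 = float(s_i[:2] @ s_j[:2]) / dist if dist > 0 else 0.0
    e2 = 1.0 if dist <= lam else 0.0
    dy = abs(s_i[1] - s_j[1])
    e3 = (1.0 if dy <= mu else 0.0) if mu_rule == "le" else (1.0 if dy > mu else 0.0)
    if xi is None:
        return e1, e2, e3
    dz = abs(s_i[2] - s_j[2]) if len(s_i) > 2 else 0.0
    e4 = 1.0 if dz <= xi else 0.0
    return e1, e2, e3, e4


# -- conditional cell-specific network --------------------------------------
def rho_from_counts(n_z, n_xz, n_yz, n_xyz) -> float:
    """Conditional association rho = n_xyz/n_z - (n_xz/n_z)(n_yz/n_z)."""
    if n_z <= 0:
        return float("nan")
    return n_xyz / n_z - (n_xz / n_z) * (n_yz / n_z)


def _neighborhood_matrix(x: np.ndarray, boxsize: float) -> np.ndarray:
    """Boolean (cells x cells): B[k, j] iff cell j lies in cell k's window.

    The window for gene value x_k is [max(0, x_k - h), x_k + h] with
    half-width h = boxsize * sd(x) / 2; a constant gene puts every cell in
    every window.
    """
    sd = x.std()
    h = boxsize * sd / 2.0
    lo = np.maximum(x[:, None] - h, 0.0)
    hi = x[:, None] + h
    return (x[None, :] >= lo) & (x[None, :] <= hi)


def conditional_rho(x_gene, y_gene, z_gene, cell_k: int, boxsize: float = 1.5):
    """rho for genes x, y given conditioning gene z in one cell.

    Neighborhood counts are taken over cells falling in the per-gene
    expression windows around cell k's values.
    """
    bx = _neighborhood_matrix(np.asarray(x_gene, float), boxsize)[cell_k]
    by = _neighborhood_matrix(np.asarray(y_gene, float), boxsize)[cell_k]
    bz = _neighborhood_matrix(np.asarray(z_gene, float), boxsize)[cell_k]
    n_z = int(bz.sum())
    return rho_from_counts(
        n_z, int((bx & bz).sum()), int((by & bz).sum()), int((bx & by & bz).sum())
    )


def _edge_significant(n_z, n_xz, n_yz, n_xyz, alpha) -> np.ndarray:
    """Vectorized significance of rho under the independence null.

    rho is standardized by its null sd sqrt(p_x (1-p_x) p_y (1-p_y) / n_z)
    with p_x = n_xz/n_z, p_y = n_yz/n_z, and compared with the standard
    normal quantile at level alpha.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_x = n_xz / n_z
        p_y = n_yz / n_z
        rho = n_xyz / n_z - p_x * p_y
        var = p_x * (1 - p_x) * p_y * (1 - p_y) / n_z
        stat = np.where(var > 0, rho / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return stat > norm.ppf(1 - alpha)


@dataclass
class ConditionalDegreeMatrix:
    """Genes x cells matrix of per-cell conditional network degrees."""

    degrees: np.ndarray  # (genes, cells) non-negative ints
    conditioning_genes: list

    def __post_init__(self):
        m = self.degrees.shape[0]
        if np.any(self.degrees < 0) or np.any(self.degrees > m - 1):
            raise ValueError("degrees must lie in [0, n_genes - 1]")


def conditional_degree_matrix(
    counts: np.ndarray,
    alpha: float = 0.5,
    boxsize: float = 1.5,
    kk: int = 1,
    conditioning_genes=None,
) -> ConditionalDegreeMatrix:
    """Per-cell conditional gene-association degrees V[i, k] = sum_j c_ijk.

    When `conditioning_genes` is None the kk hub genes are picked by the
    marginal degree of an unconditional cell-specific pass.  An edge (i, j)
    exists in cell k iff the standardized rho given any conditioning gene
    exceeds the normal quantile at level alpha; pairs involving a
    conditioning gene are excluded.
    """
    counts = np.asarray(counts, dtype=float)  # cells x genes
    n, m = counts.shape
    nbr = np.stack([_neighborhood_matrix(counts[:, g], boxsize) for g in range(m)])
    if conditioning_genes is None:
        # unconditional pass: rho0 = n_xy/n - (n_x/n)(n_y/n), same threshold
        marg = nbr.sum(axis=2)  # (m, n): n_x per cell
        hub_score = np.zeros(m)
        for x in range(m):
            for y in range(x + 1, m):
                both = (nbr[x] & nbr[y]).sum(axis=1)
                sig = _edge_significant(
                    np.full(n, float(n)), marg[x], marg[y], both, alpha
                )
                hub_score[x] += sig.sum()
                hub_score[y] += sig.sum()
        conditioning_genes = list(np.argsort(-hub_score, kind="stable")[:kk])
    cond = [int(z) for z in conditioning_genes]
    degrees = np.zeros((m, n), dtype=int)
    others = [g for g in range(m) if g not in cond]
    for z in cond:
        n_z = nbr[z].sum(axis=1).astype(float)  # per cell k
        nz_with = {x: (nbr[x] & nbr[z]).sum(axis=1) for x in others}
        for ii, x in enumerate(others):
            for y in others[ii + 1 :]:
                n_xyz = (nbr[x] & nbr[y] & nbr[z]).sum(axis=1)
                sig = _edge_significant(n_z, nz_with[x], nz_with[y], n_xyz, alpha)
                degrees[x] += sig
                degrees[y] += sig
    if len(cond) > 1:
        degrees = np.minimum(degrees, m - 1)  # union over conditioning genes
    return ConditionalDegreeMatrix(degrees=degrees, conditioning_genes=cond)


# -- graph assembly ----------------------------------------------------------
def _knn_pairs(dist: np.ndarray, k: int) -> np.ndarray:
    """Deterministic symmetric kNN pairs from a full distance matrix.

    Ties break by node index; the self column is excluded; the union of
    directed kNN relations is symmetrized.
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"knn_edges={k} must be < n_nodes={n}")
    pairs = set()
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        order = order[order != i][:k]
        for j in order:
            pairs.add((min(i, int(j)), max(i, int(j))))
    und = np.array(sorted(pairs), dtype=int)
    return np.vstack([und, und[:, ::-1]])


def _cosine_distance_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    sim = (x @ x.T) / np.outer(norms, norms)
    return 1.0 - sim


def build_view_graph(view_name, node_features, aux_features, config, within=None):
    """Assemble a ViewGraph for one view.

    `aux_features` is the view's auxiliary data: visual features (HSG),
    coordinates (SLG/SLG3D) or expression features w (GAG).  `within`
    optionally restricts candidate neighbors to groups (e.g. slices for a 2-D
    multi-slice SLG).  Bounded channels are made strictly positive by the
    affine map f -> (f+1)/2 + eps; the unbounded SLG dot/distance channel is
    scaled by its max absolute value first; binary indicators are shifted by
    eps.
    """
    node_features = np.asarray(node_features, dtype=float)
    aux = np.asarray(aux_features, dtype=float)
    n = node_features.shape[0]
    eps = config.edge_eps
    is_slg = view_name.upper().startswith("SLG")
    if is_slg:
        dist = np.linalg.norm(aux[:, None] - aux[None], axis=-1)
    else:
        dist = _cosine_distance_matrix(aux)
    if within is not None:
        within = np.asarray(within)
        dist = dist.copy()
        dist[within[:, None] != within[None, :]] = np.inf
    edges = _knn_pairs(dist, config.knn_edges)
    use_3d = is_slg and aux.shape[1] == 3
    xi = config.slg_xi
    if use_3d and xi is None:
        zs = np.unique(aux[:, 2])
        xi = float(np.min(np.diff(zs))) if len(zs) > 1 else 0.0
    raw = []
    for i, j in edges:
        if is_slg:
            f = location_edge_features(
                aux[i], aux[j], config.slg_lambda, config.slg_mu,
                xi=xi if use_3d else None, mu_rule=config.mu_rule,
            )
        else:
            f = similarity_edge_features(aux[i], aux[j])
        raw.append(f)
    raw = np.array(raw)
    pos = raw.copy()
    if is_slg:
        scale = np.max(np.abs(raw[:, 0])) or 1.0
        pos[:, 0] = (raw[:, 0] / scale + 1.0) / 2.0 + eps
        pos[:, 1:] = raw[:, 1:] + eps
    else:
        pos[:, 0] = (raw[:, 0] + 1.0) / 2.0 + eps
        pos[:, 1] = raw[:, 1] + eps
        pos[:, 2] = (raw[:, 2] + 1.0) / 2.0 + eps
    return ViewGraph(
        view_name=view_name,
        node_features=node_features,
        edges=edges,
        edge_features=pos,
        raw_edge_features=raw,
    )
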