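"""Spatial-domain clustering, SPE denoising, SVG/SPVG/SDG calling, pipeline.

Clustering is k-means on the fused embedding with the cluster count chosen
by the smallest Davies-Bouldin index over a scanned range.  Spatial
pseudo-expression (SPE) replaces each spot's counts by the mean over its
k (default 15) nearest neighbors in embedding space, self excluded.  Genes
are then classified per modality by one-vs-rest Wilcoxon rank-sum tests with
Benjamini-Hochberg correction: SVGs are differential in raw counts, SPVGs in
SPE, and spatial dark genes (SDGs) are differential in SPE but *not* in raw
counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.stats.multitest import multipletests

from . import __version__
from .config import RunConfig
from .data import SpotDataset, write_tsv_matrix
from .egat import train_egat
from .expr_ae import select_hvg, train_expr_ae
from .fusion import fuse_views
from .graphs import build_view_graph, conditional_degree_matrix
from .simulate import SimTruth  # noqa: F401  (re-exported for pipeline users)

log = logging.getLogger("spotfuse")


# -- metrics (thin wrappers kept for a stable surface) -----------------------
def ari(labels_a, labels_b) -> float:
    return float(adjusted_rand_score(labels_a, labels_b))


def asw(embedding, labels) -> float:
    return float(silhouette_score(embedding, labels))


def dbi(embedding, labels) -> float:
    return float(davies_bouldin_score(embedding, labels))


# -- clustering ---------------------------------------------------------------
def select_k_dbi(r: np.ndarray, k_range, seed: int = 0) -> int:
    """Smallest-DBI cluster count over k_range (ties -> smaller k)."""
    r = np.asarray(r, dtype=float)
    if np.allclose(r, r[0]):
        raise ValueError("degenerate embedding: all rows identical")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > len(r) - 1 for k in ks):
        raise ValueError("k_range must lie within [2, n_spots - 1]")
    best_k, best = None, np.inf
    for k in ks:
        lab = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(r)
        score = davies_bouldin_score(r, lab) if len(set(lab)) > 1 else np.inf
        if score < best - 1e-12:
            best, best_k = score, k
    return best_k


def cluster_spots(r: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels renumbered by descending cluster size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    r = np.asarray(r, dtype=float)
    for attempt in range(20):
        lab = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt).fit_predict(r)
        if len(set(lab)) == k:
            break
    sizes = np.bincount(lab, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[lab]


# -- spatial pseudo-expression ------------------------------------------------
@dataclass
class SpeMatrix:
    """k-NN-averaged counts plus the neighbor table that produced them."""

    spe: np.ndarray  # spots x genes
    k_nn: int
    neighbors: np.ndarray  # spots x k_nn indices


def compute_spe(
    r: np.ndarray, counts: np.ndarray, k_nn: int = 15, include_self: bool = False
) -> SpeMatrix:
    """Mean raw counts over each spot's k_nn nearest embedding neighbors.

    Neighbors are ranked by Euclidean distance in R-space with deterministic
    index tie-break; the spot itself is excluded unless include_self.
    """
    r = np.asarray(r, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = r.shape[0]
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be < n_spots={n}")
    d = np.linalg.norm(r[:, None] - r[None], axis=-1)
    idx = np.arange(n)
    nbrs = np.empty((n, k_nn), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, d[i]))
        if not include_self:
            order = order[order != i]
        nbrs[i] = order[:k_nn]
    spe = counts[nbrs].mean(axis=1)
    return SpeMatrix(spe=spe, k_nn=k_nn, neighbors=nbrs)


# -- SVG / SPVG / SDG calling -------------------------------------------------
@dataclass
class SdgReport:
    """Per-gene-per-cluster differential stats and gene-level classes."""

    per_cluster: pd.DataFrame  # gene, cluster, modality, log2fc, pvalue, qvalue
    genes: pd.DataFrame  # gene, is_svg, is_spvg, is_sdg, class

    def to_tsv(self, path):
        self.genes.to_csv(path, sep="\t", index=False)


def _one_vs_rest_stats(matrix, labels, clusters):
    """log2FC and rank-sum p per (gene, cluster); constant genes -> p = 1."""
    eps = 1e-9
    rows = []
    for c in clusters:
        inside = labels == c
        m_in = matrix[inside].mean(axis=0)
        m_out = matrix[~inside].mean(axis=0)
        lfc = np.log2((m_in + eps) / (m_out + eps))
        for g in range(matrix.shape[1]):
            col = matrix[:, g]
            if np.ptp(col) == 0:
                p = 1.0
            else:
                p = float(ranksums(col[inside], col[~inside]).pvalue)
            rows.append((g, c, lfc[g], p))
    return rows


def call_sdgs(
    counts: np.ndarray,
    spe: np.ndarray,
    cluster_labels: np.ndarray,
    fdr: float = 0.05,
    lfc_min: float = 0.25,
    gene_ids=None,
) -> SdgReport:
    """Classify genes as SVG / SPVG / SDG / none from raw and SPE contrasts.

    One-vs-rest rank-sum per cluster in each modality, BH correction within
    modality; a gene is SVG (raw-differential) or SPVG (SPE-differential)
    when some cluster reaches q < fdr and |log2FC| >= lfc_min.  SDGs are
    SPE-differential genes with no raw signal (SPVG and not SVG).
    """
    counts = np.asarray(counts, dtype=float)
    spe = np.asarray(spe, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    clusters = np.unique(cluster_labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    if np.min(np.bincount(cluster_labels.astype(int))) < 5:
        raise ValueError("every cluster needs >= 5 spots")
    g = counts.shape[1]
    ids = list(gene_ids) if gene_ids is not None else list(range(g))
    frames = []
    flags = {}
    for modality, mat in (("raw", counts), ("spe", spe)):
        rows = _one_vs_rest_stats(mat, cluster_labels, clusters)
        df = pd.DataFrame(rows, columns=["gene", "cluster", "log2fc", "pvalue"])
        df["modality"] = modality
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        frames.append(df)
        hit = (df["qvalue"] < fdr) & (df["log2fc"].abs() >= lfc_min)
        flags[modality] = df.loc[hit, "gene"].unique()
    per_cluster = pd.concat(frames, ignore_index=True)
    per_cluster["gene"] = [ids[i] for i in per_cluster["gene"]]
    is_svg = np.isin(np.arange(g), flags["raw"])
    is_spvg = np.isin(np.arange(g), flags["spe"])
    all_zero = ~counts.any(axis=0)
    is_svg &= ~all_zero
    is_spvg &= ~all_zero
    is_sdg = is_spvg & ~is_svg
    cls = np.where(
        is_sdg, "SDG",
        np.where(is_svg & is_spvg, "SPVG", np.where(is_svg, "SVG", "none")),
    )
    genes = pd.DataFrame(
        {
            "gene": ids,
            "is_svg": is_svg,
            "is_spvg": is_spvg,
            "is_sdg": is_sdg,
            "class": cls,
        }
    )
    return SdgReport(per_cluster=per_cluster, genes=genes)


# -- end-to-end pipeline ------------------------------------------------------
@dataclass
class PipelineResult:
    fused: np.ndarray
    view_embeddings: dict
    clusters: np.ndarray
    spe: SpeMatrix
    sdg_report: SdgReport
    x0: np.ndarray
    manifest: dict = field(default_factory=dict)


def _weak_label_codes(dataset: SpotDataset, frac: float, rng) -> np.ndarray | None:
    if dataset.labels is None:
        return None
    codes, classes = dataset.label_codes()
    if not classes:
        return None
    labeled = np.nonzero(codes >= 0)[0]
    keep = rng.choice(labeled, size=int(round(frac * labeled.size)), replace=False)
    weak = -np.ones_like(codes)
    weak[np.sort(keep)] = codes[np.sort(keep)]
    return weak


def run_pipeline(
    dataset: SpotDataset,
    config: RunConfig | None = None,
    outdir=None,
    visual_features: np.ndarray | None = None,
    use_labels: bool = True,
    mode_3d: bool | None = None,
    allow_single_view: bool = False,
) -> PipelineResult:
    """Features -> view graphs -> EGAT per view -> fusion -> clustering ->
    SPE -> SDG report.

    Views are auto-detected: SLG always (coordinates required), GAG from the
    expression matrix, HSG only when patches or precomputed visual features
    are available.  With slice information present the SLG becomes a 3-D
    graph with 4-channel edge features unless mode_3d=False, in which case
    neighbor search is restricted to within-slice pairs.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    if dataset.coords is None:
        raise ValueError("pipeline requires spot coordinates")
    weak = _weak_label_codes(dataset, cfg.label_frac, rng) if use_labels else None

    # Step 1 — feature extraction
    hvg_counts, hvg_idx = select_hvg(
        dataset.counts, min(cfg.hvg_count, dataset.n_genes), dataset.gene_ids
    )
    x0, _ = train_expr_ae(hvg_counts, cfg, seed=cfg.seed)

    # Step 2 — view graphs + EGAT
    multi_slice = dataset.slice_id is not None and len(set(dataset.slice_id)) > 1
    if mode_3d is None:
        mode_3d = multi_slice
    graphs = {}
    if multi_slice and mode_3d:
        coords = dataset.coords
        if coords.shape[1] == 2:
            zs = dataset.slice_id.astype(float)
            coords = np.column_stack([coords, zs])
        graphs["SLG3D"] = build_view_graph("SLG3D", x0, coords, cfg)
    elif multi_slice:
        graphs["SLG"] = build_view_graph(
            "SLG", x0, dataset.coords[:, :2], cfg, within=dataset.slice_id
        )
    else:
        graphs["SLG"] = build_view_graph("SLG", x0, dataset.coords[:, :2], cfg)

    n_gag = min(cfg.gag_genes, hvg_counts.shape[1])
    gag_counts, _ = select_hvg(hvg_counts, n_gag)
    cdm = conditional_degree_matrix(
        gag_counts, alpha=cfg.ccsn_alpha, boxsize=cfg.ccsn_boxsize, kk=cfg.ccsn_kk
    )
    v_embed, _ = train_expr_ae(cdm.degrees.T, cfg, seed=cfg.seed + 1)
    graphs["GAG"] = build_view_graph("GAG", v_embed, x0, cfg)

    if visual_features is None and dataset.patches is not None:
        from .visual import train_contrastive

        visual_features, _ = train_contrastive(
            dataset.patches, cfg, seed=cfg.seed, labels=weak
        )
    if visual_features is not None:
        graphs["HSG"] = build_view_graph("HSG", x0, visual_features, cfg)

    if len(graphs) < 2 and not allow_single_view:
        raise ValueError(
            f"only {list(graphs)} available; fusion needs >= 2 views "
            "(pass allow_single_view=True for a single-view run)"
        )

    embeddings = {}
    for i, (name, graph) in enumerate(sorted(graphs.items())):
        embeddings[name], _ = train_egat(graph, weak, cfg, seed=cfg.seed + 10 + i)

    # Step 3 — fusion
    if len(embeddings) >= 2:
        fused, _ = fuse_views(
            [embeddings[k] for k in sorted(embeddings)], weak, cfg, seed=cfg.seed + 20
        )
    else:
        fused = next(iter(embeddings.values()))

    # downstream
    if cfg.cluster_k is not None:
        k = cfg.cluster_k
    else:
        lo, hi = cfg.k_range
        k = select_k_dbi(fused, range(lo, hi + 1), seed=cfg.seed)
    clusters = cluster_spots(fused, k, seed=cfg.seed)
    spe = compute_spe(fused, dataset.counts, k_nn=min(cfg.spe_k, dataset.n_spots - 1))
    try:
        report = call_sdgs(
            dataset.counts, spe.spe, clusters, cfg.fdr, cfg.lfc_min, dataset.gene_ids
        )
    except ValueError as err:  # e.g. a tiny cluster at desk scale
        log.warning("SDG calling skipped: %s", err)
        report = None
    manifest = {
        "package": "spotfuse",
        "version": __version__,
        "config": cfg.asdict(),
        "views": sorted(graphs),
        "mode_3d": bool(mode_3d),
        "n_spots": dataset.n_spots,
        "n_genes": dataset.n_genes,
        "cluster_k": int(k),
    }
    result = PipelineResult(
        fused=fused,
        view_embeddings=embeddings,
        clusters=clusters,
        spe=spe,
        sdg_report=report,
        x0=x0,
        manifest=manifest,
    )
    if outdir is not None:
        persist_result(result, dataset, outdir)
    return result


def persist_result(result: PipelineResult, dataset: SpotDataset, outdir):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv_matrix(out / "fused_embedding.tsv", result.fused, dataset.spot_ids)
    for name, emb in result.view_embeddings.items():
        write_tsv_matrix(out / f"embedding_{name}.tsv", emb, dataset.spot_ids)
    pd.DataFrame({"id": dataset.spot_ids, "cluster": result.clusters}).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    write_tsv_matrix(
        out / "spe.tsv", result.spe.spe, dataset.spot_ids, list(dataset.gene_ids)
    )
    if result.sdg_report is not None:
        result.sdg_report.to_tsv(out / "sdg_report.tsv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")
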