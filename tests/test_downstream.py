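"""Clustering, SPE, SVG/SPVG/SDG calling, metrics and pipeline reproducibility."""

import dataclasses

import numpy as np
import pytest

from spotfuse.config import RunConfig
from spotfuse.downstream import (
    ari,
    asw,
    call_sdgs,
    cluster_spots,
    compute_spe,
    dbi,
    run_pipeline,
    select_k_dbi,
)
from spotfuse.simulate import plant_dark_genes, simulate_srt


def _blobs(rng, k, n_per=40, sep=8.0):
    centers = rng.normal(size=(k, 3)) * sep
    pts = np.vstack([c + rng.normal(size=(n_per, 3)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


# -- model selection ----------------------------------------------------------
@pytest.mark.parametrize("k_true", [2, 3])
def test_dbi_selects_true_blob_count(k_true):
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        pts, _ = _blobs(rng, k_true)
        hits += select_k_dbi(pts, range(2, 7), seed=seed) == k_true
    assert hits >= 9


def test_k_range_singleton():
    rng = np.random.default_rng(0)
    pts, _ = _blobs(rng, 4)
    assert select_k_dbi(pts, [4], seed=0) == 4


def test_degenerate_embedding_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        select_k_dbi(np.ones((20, 3)), range(2, 4))


# -- clustering ---------------------------------------------------------------
def test_cluster_blobs_high_ari():
    rng = np.random.default_rng(1)
    pts, truth = _blobs(rng, 3)
    lab = cluster_spots(pts, 3, seed=0)
    assert ari(truth, lab) >= 0.95


def test_cluster_duplicates_same_label_and_sizes_descending():
    rng = np.random.default_rng(2)
    pts, _ = _blobs(rng, 2, n_per=30)
    pts[5] = pts[4]
    lab = cluster_spots(pts, 2, seed=0)
    assert lab[4] == lab[5]
    sizes = np.bincount(lab)
    assert np.all(np.diff(sizes) <= 0)  # renumbered by descending size


def test_cluster_deterministic():
    rng = np.random.default_rng(3)
    pts, _ = _blobs(rng, 2)
    np.testing.assert_array_equal(cluster_spots(pts, 2, 7), cluster_spots(pts, 2, 7))


# -- metrics vs textbook implementations -------------------------------------
def _silhouette_naive(x, labels):
    n = len(x)
    d = np.linalg.norm(x[:, None] - x[None], axis=-1)
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = d[i, same].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def _dbi_naive(x, labels):
    ks = sorted(set(labels))
    cents = np.array([x[labels == c].mean(axis=0) for c in ks])
    s = np.array(
        [np.linalg.norm(x[labels == c] - cents[i], axis=1).mean()
         for i, c in enumerate(ks)]
    )
    total = 0.0
    for i in range(len(ks)):
        total += max(
            (s[i] + s[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(ks)) if j != i
        )
    return total / len(ks)


def test_asw_and_dbi_match_naive_implementations():
    rng = np.random.default_rng(4)
    pts, truth = _blobs(rng, 3, n_per=17, sep=3.0)
    assert asw(pts, truth) == pytest.approx(_silhouette_naive(pts, truth), abs=1e-8)
    assert dbi(pts, truth) == pytest.approx(_dbi_naive(pts, truth), abs=1e-8)


# -- SPE ----------------------------------------------------------------------
def test_spe_identical_counts_identity(rng):
    counts = np.tile(rng.integers(0, 9, size=12), (30, 1))
    spe = compute_spe(rng.normal(size=(30, 3)), counts, k_nn=5)
    np.testing.assert_allclose(spe.spe, counts)


def test_spe_collinear_nearest_neighbor():
    r = np.array([[0.0], [1.0], [3.0]])
    counts = np.array([[10, 0], [0, 10], [5, 5]])
    spe = compute_spe(r, counts, k_nn=1)
    np.testing.assert_array_equal(spe.spe[0], counts[1])
    np.testing.assert_array_equal(spe.spe[1], counts[0])
    np.testing.assert_array_equal(spe.spe[2], counts[1])


def test_spe_convex_bounds(rng):
    counts = rng.poisson(6, size=(50, 8)).astype(float)
    spe = compute_spe(rng.normal(size=(50, 4)), counts, k_nn=7)
    assert np.all(spe.spe >= counts.min(axis=0) - 1e-12)
    assert np.all(spe.spe <= counts.max(axis=0) + 1e-12)


def test_spe_k_too_large():
    with pytest.raises(ValueError):
        compute_spe(np.zeros((5, 2)), np.zeros((5, 3)), k_nn=5)


def test_spe_variance_reduction_factor(rng):
    counts = rng.poisson(10, size=(400, 20)).astype(float)
    spe = compute_spe(rng.normal(size=(400, 8)), counts, k_nn=15)
    ratio = counts.var(axis=0) / spe.spe.var(axis=0)
    assert np.all(ratio > 15 / 1.5) and np.all(ratio < 15 * 1.5)


# -- SDG calling --------------------------------------------------------------
def test_constant_gene_classified_none(rng):
    counts = rng.poisson(5, size=(60, 4)).astype(float)
    counts[:, 2] = 3.0
    labels = np.repeat([0, 1], 30)
    rep = call_sdgs(counts, counts, labels)
    assert rep.genes.loc[2, "class"] == "none"


def test_strong_raw_marker_never_sdg(rng):
    labels = np.repeat([0, 1], 40)
    counts = rng.poisson(5, size=(80, 6)).astype(float)
    counts[labels == 0, 0] += 30  # blatant raw marker
    spe = counts.copy()
    rep = call_sdgs(counts, spe, labels, lfc_min=0.0)
    assert rep.genes.loc[0, "is_svg"]
    assert not rep.genes.loc[0, "is_sdg"]


def test_gene_classes_partition(rng):
    counts = rng.poisson(5, size=(80, 20)).astype(float)
    labels = np.repeat([0, 1], 40)
    rep = call_sdgs(counts, counts + rng.normal(0, 0.1, counts.shape), labels)
    assert set(rep.genes["class"]) <= {"SVG", "SPVG", "SDG", "none"}
    assert not np.any(rep.genes.is_sdg & rep.genes.is_svg)
    assert rep.genes.shape[0] == 20


def test_too_few_clusters_rejected(rng):
    counts = rng.poisson(5, size=(20, 3)).astype(float)
    with pytest.raises(ValueError):
        call_sdgs(counts, counts, np.zeros(20, dtype=int))


# -- pipeline reproducibility -------------------------------------------------
def test_pipeline_rerun_identical_outputs(tmp_path, desk_config):
    ds, truth = simulate_srt(
        n_spots=120, n_genes=60, k_domains=2, nb_mean_shift=4.0, seed=9,
        with_patches=False,
    )
    cfg = dataclasses.replace(
        desk_config, ae_epochs=20, egat_epochs=10, gam_epochs=10, cluster_k=2,
        gag_genes=30, seed=11,
    )
    run_pipeline(ds, cfg, outdir=tmp_path / "a")
    run_pipeline(ds, cfg, outdir=tmp_path / "b")
    for name in ("fused_embedding.tsv", "clusters.tsv", "spe.tsv", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name
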