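"""Edge-feature arithmetic, the conditional association statistic, kNN graphs."""

import numpy as np
import pytest

from spotfuse.config import RunConfig
from spotfuse.graphs import (
    ConditionalDegreeMatrix,
    build_view_graph,
    conditional_degree_matrix,
    conditional_rho,
    location_edge_features,
    rho_from_counts,
    similarity_edge_features,
)


# -- similarity features ------------------------------------------------------
def test_similarity_identity_vector():
    assert similarity_edge_features([1, 2, 2], [1, 2, 2]) == pytest.approx((1, 1, 1))


def test_similarity_orthogonal_pair():
    e1, e2, e3 = similarity_edge_features([1.0, 0.0], [0.0, 1.0])
    assert e1 == pytest.approx(0.0)
    assert e2 == pytest.approx(np.exp(-np.sqrt(2)), abs=1e-4)
    assert e3 == pytest.approx(-1.0)


def test_similarity_constant_vector_rule():
    _, _, e3 = similarity_edge_features([1.0, 1.0, 1.0], [3.0, 1.0, 2.0])
    assert e3 == 0.0


def test_similarity_errors():
    with pytest.raises(ValueError, match="zero vector"):
        similarity_edge_features([0.0, 0.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="length"):
        similarity_edge_features([1.0], [2.0])


# -- location features --------------------------------------------------------
def test_location_published_threshold_case():
    """(0,0)-(3,4) at the published optimum mu=10, lambda=200."""
    assert location_edge_features((0, 0), (3, 4), lam=200, mu=10) == (0.0, 1.0, 1.0)


def test_location_distant_pair():
    e = location_edge_features((100, 100), (400, 500), lam=200, mu=10)
    assert e == (180.0, 0.0, 0.0)


def test_location_3d_slice_gap_threshold():
    z_gap = 100.0
    near = location_edge_features((0, 0, 0), (3, 4, z_gap), 200, 10, xi=150.0)
    far = location_edge_features((0, 0, 0), (3, 4, 2 * z_gap), 200, 10, xi=150.0)
    assert near[3] == 1.0 and far[3] == 0.0


def test_location_coincident_points_error():
    with pytest.raises(ValueError, match="coincident"):
        location_edge_features((1, 1), (1, 1), 200, 10)


def test_location_mu_rule_flip():
    le = location_edge_features((0, 0), (0, 30), 200, 10, mu_rule="le")
    gt = location_edge_features((0, 0), (0, 30), 200, 10, mu_rule="gt")
    assert le[2] == 0.0 and gt[2] == 1.0


# -- conditional rho ----------------------------------------------------------
def test_rho_from_counts_coupled():
    assert rho_from_counts(10, 5, 5, 5) == pytest.approx(0.25)


def test_rho_zero_under_product_independence():
    assert rho_from_counts(20, 10, 8, 4) == pytest.approx(0.0)


def test_rho_nan_for_empty_conditioning():
    assert np.isnan(rho_from_counts(0, 0, 0, 0))


def test_rho_bounded_over_random_configurations(rng):
    for _ in range(1000):
        n_z = int(rng.integers(1, 50))
        n_xz = int(rng.integers(0, n_z + 1))
        n_yz = int(rng.integers(0, n_z + 1))
        n_xyz = int(rng.integers(0, min(n_xz, n_yz) + 1))
        r = rho_from_counts(n_z, n_xz, n_yz, n_xyz)
        assert -1.0 <= r <= 1.0


def _naive_rho(x, y, z, k, boxsize):
    """O(cells^2) counting reference for conditional_rho."""
    def inside(v, center, sd):
        h = boxsize * sd / 2.0
        return (v >= max(0.0, center - h)) and (v <= center + h)

    n = len(x)
    sx, sy, sz = np.std(x), np.std(y), np.std(z)
    nz = nxz = nyz = nxyz = 0
    for j in range(n):
        in_z = inside(z[j], z[k], sz)
        in_x = inside(x[j], x[k], sx)
        in_y = inside(y[j], y[k], sy)
        nz += in_z
        nxz += in_x and in_z
        nyz += in_y and in_z
        nxyz += in_x and in_y and in_z
    return nxyz / nz - (nxz / nz) * (nyz / nz)


def test_conditional_rho_matches_naive_counting(rng):
    for trial in range(10):
        x = rng.poisson(5, 20).astype(float)
        y = rng.poisson(5, 20).astype(float)
        z = rng.poisson(5, 20).astype(float)
        for k in (0, 7, 19):
            assert conditional_rho(x, y, z, k, 1.5) == pytest.approx(
                _naive_rho(x, y, z, k, 1.5)
            )


# -- conditional degree matrix ------------------------------------------------
def test_degree_matrix_identical_cells_gives_zero():
    counts = np.tile([3.0, 5.0, 2.0], (10, 1))  # all cells identical
    cdm = conditional_degree_matrix(counts)
    assert np.all(cdm.degrees == 0)


def test_degree_matrix_deterministic(rng):
    counts = rng.poisson(4, size=(30, 8))
    a = conditional_degree_matrix(counts)
    b = conditional_degree_matrix(counts)
    np.testing.assert_array_equal(a.degrees, b.degrees)
    assert a.conditioning_genes == b.conditioning_genes


def test_degree_matrix_correlated_pair_detected(rng):
    """Two strongly coupled genes gain degree; an independent gene does not."""
    n = 60
    base = rng.poisson(10, n).astype(float)
    counts = np.column_stack([base, base + rng.poisson(1, n),
                              rng.poisson(10, n), rng.poisson(10, n)])
    cdm = conditional_degree_matrix(counts, alpha=0.5, kk=1,
                                    conditioning_genes=[3])
    coupled = cdm.degrees[0].mean() + cdm.degrees[1].mean()
    lone = cdm.degrees[2].mean()
    assert coupled > 2 * lone


def test_degree_bounds_invariant(rng):
    counts = rng.poisson(4, size=(25, 6))
    cdm = conditional_degree_matrix(counts)
    assert isinstance(cdm, ConditionalDegreeMatrix)
    assert cdm.degrees.min() >= 0 and cdm.degrees.max() <= 5


# -- graph assembly -----------------------------------------------------------
def test_slg_collinear_knn_oracle():
    cfg = RunConfig(knn_edges=1, slg_lambda=200, slg_mu=10)
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    g = build_view_graph("SLG", np.eye(4), coords, cfg)
    und = {tuple(sorted(e)) for e in g.edges.tolist()}
    assert und == {(0, 1), (1, 2), (2, 3)}


def test_graph_symmetric_with_equal_features(slg_graph):
    feat = {}
    for (i, j), f in zip(slg_graph.edges.tolist(), slg_graph.edge_features):
        feat[(i, j)] = f
    for (i, j), f in feat.items():
        assert (j, i) in feat
        np.testing.assert_allclose(f, feat[(j, i)])


def test_edge_features_strictly_positive(slg_graph):
    assert np.all(slg_graph.edge_features > 0)


def test_slg_binary_channels_pre_shift(slg_graph):
    raw = slg_graph.raw_edge_features
    for c in (1, 2):
        assert set(np.unique(raw[:, c])) <= {0.0, 1.0}


def test_hsg_identical_features_ties_broken(rng):
    cfg = RunConfig(knn_edges=2)
    v = np.tile(rng.normal(size=5), (8, 1))  # identical visual features
    g = build_view_graph("HSG", rng.normal(size=(8, 4)), v, cfg)
    assert np.allclose(g.raw_edge_features[:, 0], 1.0)
    assert np.allclose(g.raw_edge_features[:, 1], 1.0)
    assert g.edges.shape[0] > 0


def test_knn_too_large_rejected(rng):
    cfg = RunConfig(knn_edges=10)
    with pytest.raises(ValueError, match="knn"):
        build_view_graph("SLG", np.eye(5), rng.normal(size=(5, 2)), cfg)


def test_graph_tsv_roundtrip(tmp_path, slg_graph):
    slg_graph.save(tmp_path / "SLG")
    back = type(slg_graph).load(tmp_path / "SLG", "SLG")
    np.testing.assert_array_equal(slg_graph.edges, back.edges)
    np.testing.assert_allclose(slg_graph.edge_features, back.edge_features)
    np.testing.assert_allclose(slg_graph.node_features, back.node_features, atol=1e-9)
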