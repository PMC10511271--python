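"""EGAT: DS normalization invariants, dense-oracle equivalence, losses, training."""

import numpy as np
import pytest

from spotfuse.config import RunConfig
from spotfuse.egat import (
    EgatLayerParams,
    decode_adjacency,
    ds_normalize,
    egat_layer,
    egat_loss,
    train_egat,
)


# -- DS normalization ---------------------------------------------------------
def test_ds_identity_fixed_point():
    e = np.eye(4)
    np.testing.assert_allclose(ds_normalize(e), np.eye(4), atol=1e-12)


def test_ds_uniform_two_by_two():
    out = ds_normalize(np.ones((2, 2)))
    np.testing.assert_allclose(out, np.full((2, 2), 0.5), atol=1e-12)


def test_ds_random_channels_symmetric_row_stochastic(rng):
    e = rng.uniform(0.1, 2.0, size=(6, 6, 3))
    out = ds_normalize(e)
    for p in range(3):
        ch = out[:, :, p]
        np.testing.assert_allclose(ch.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(ch, ch.T, atol=1e-10)
        assert np.all(ch >= 0)


def test_ds_isolated_node_rejected():
    e = np.ones((3, 3))
    e[1, :] = 0.0
    with pytest.raises(ValueError, match="isolated"):
        ds_normalize(e)


# -- dense brute-force oracle -------------------------------------------------
from oracles import oracle_ds as _oracle_ds
from oracles import oracle_egat_layer as _oracle_egat_layer
from oracles import random_graph_tensor as _random_graph_tensor


def test_egat_layer_matches_dense_oracle(rng):
    """Vectorized layer equals the loop-based reference on small graphs."""
    for draw in range(50):
        n = int(rng.integers(2, 7))
        p_ch = int(rng.integers(1, 4))
        f_in, f_out = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        x = rng.normal(size=(n, f_in))
        e = _random_graph_tensor(rng, n, p_ch)
        params = EgatLayerParams(
            w=rng.normal(size=(f_in, f_out)) * 0.5,
            a=rng.normal(size=2 * f_out) * 0.5,
            leaky_slope=0.2,
        )
        x_ref, e_ref = _oracle_egat_layer(x, e, params)
        x_got, e_got = egat_layer(x, e, params)
        assert np.max(np.abs(x_got - x_ref)) < 1e-5
        assert np.max(np.abs(e_got - e_ref)) < 1e-5


def test_egat_layer_zero_attention_is_pure_ds(rng):
    """With a = 0 the attention is constant, so alpha = DS(E_prev)."""
    n = 5
    e = _random_graph_tensor(rng, n, 2)
    x = rng.normal(size=(n, 3))
    params = EgatLayerParams(w=np.eye(3), a=np.zeros(6))
    _, e_next = egat_layer(x, e, params)
    np.testing.assert_allclose(e_next, ds_normalize(e), atol=1e-10)


def test_egat_layer_complete_graph_mean_limit(rng):
    """Uniform edge features on a complete graph with a=0 average neighbors."""
    n = 4
    e = np.ones((n, n, 1)) - np.eye(n)[:, :, None]
    x = rng.normal(size=(n, 3))
    params = EgatLayerParams(w=np.eye(3), a=np.zeros(6))
    out, _ = egat_layer(x, e, params)
    alpha = ds_normalize(e[:, :, 0])
    expected = alpha @ x
    expected = np.where(expected > 0, expected, np.exp(np.minimum(expected, 0)) - 1)
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_egat_layer_permutation_equivariant(rng):
    n = 6
    x = rng.normal(size=(n, 4))
    e = _random_graph_tensor(rng, n, 2)
    params = EgatLayerParams(
        w=rng.normal(size=(4, 3)), a=rng.normal(size=6) * 0.3
    )
    out, _ = egat_layer(x, e, params)
    perm = rng.permutation(n)
    out_p, _ = egat_layer(x[perm], e[perm][:, perm], params)
    np.testing.assert_allclose(out_p, out[perm], atol=1e-6)


# -- decoder and loss ---------------------------------------------------------
def test_decode_zero_embedding_gives_half():
    np.testing.assert_allclose(decode_adjacency(np.zeros((3, 2))), 0.5)


def test_decode_orthonormal_rows():
    a = decode_adjacency(np.eye(3))
    off = a[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 0.5)
    np.testing.assert_allclose(np.diag(a), 1 / (1 + np.exp(-1)))
    np.testing.assert_array_equal(a, a.T)


def test_egat_loss_perfect_reconstruction():
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    total, parts = egat_loss(a, np.clip(a, 1e-7, 1 - 1e-7))
    assert parts["recon"] == pytest.approx(0.0, abs=1e-5)


def test_egat_loss_half_probabilities_bce():
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    total, parts = egat_loss(a, np.full((2, 2), 0.5))
    assert parts["recon"] == pytest.approx(np.log(2), abs=1e-12)


def test_egat_loss_correct_labels_zero_cls():
    a = np.zeros((3, 3))
    y = np.array([0, 1, 0])
    y_prime = np.eye(2)[y]
    total, parts = egat_loss(a, np.full((3, 3), 0.5), y, y_prime, np.arange(3))
    assert parts["cls"] == pytest.approx(0.0, abs=1e-9)


def test_egat_loss_weight_is_linear():
    a = np.zeros((2, 2))
    y = np.array([0, 1])
    y_prime = np.array([[0.7, 0.3], [0.4, 0.6]])
    t1, p1 = egat_loss(a, np.full((2, 2), 0.5), y, y_prime, np.arange(2), weight=8.0)
    t2, p2 = egat_loss(a, np.full((2, 2), 0.5), y,
                       np.array([[0.6, 0.4], [0.4, 0.6]]), np.arange(2), weight=8.0)
    assert t1 - t2 == pytest.approx(8.0 * (p1["cls"] - p2["cls"]))


def test_egat_loss_unsupervised_warns():
    a = np.zeros((2, 2))
    total, parts = egat_loss(a, np.full((2, 2), 0.5))
    assert parts["cls"] == 0.0


# -- training -----------------------------------------------------------------
def test_train_egat_loss_decreases_and_deterministic(slg_graph, two_domain_dataset,
                                                     desk_config):
    ds, truth = two_domain_dataset
    codes, _ = ds.label_codes()
    r1, losses = train_egat(slg_graph, codes, desk_config, seed=0, epochs=15)
    assert losses[-1] < losses[0]
    assert np.all(np.isfinite(r1))
    r2, _ = train_egat(slg_graph, codes, desk_config, seed=0, epochs=15)
    np.testing.assert_array_equal(r1, r2)


def test_train_egat_zero_epochs_is_forward_pass(slg_graph, desk_config):
    r, losses = train_egat(slg_graph, None, desk_config, seed=1, epochs=0)
    assert losses == []
    assert np.all(np.isfinite(r))
    r2, _ = train_egat(slg_graph, None, desk_config, seed=1, epochs=0)
    np.testing.assert_array_equal(r, r2)


def test_train_egat_label_free_contract(slg_graph, desk_config):
    r, losses = train_egat(slg_graph, None, desk_config, seed=2, epochs=5)
    assert r.shape[0] == slg_graph.n_nodes
    assert np.all(np.isfinite(r))
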