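"""Shared fixtures: desk-scale configs and small simulated datasets."""

import numpy as np
import pytest

from spotfuse.config import RunConfig
from spotfuse.simulate import simulate_srt


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale training protocol used by fixture tests (see docs/methods.md)."""
    return RunConfig(
        ae_lr=1e-3, ae_epochs=60, ae_hidden=128, egat_epochs=40,
        gag_genes=50, simclr_epochs=6, simclr_batch=32,
    )


@pytest.fixture(scope="session")
def two_domain_dataset():
    """300 spots, 2 domains, strong (4x) SVG shift, with patches."""
    ds, truth = simulate_srt(
        n_spots=300, n_genes=100, k_domains=2, nb_mean_shift=4.0, seed=1
    )
    return ds, truth


@pytest.fixture(scope="session")
def expr_features(two_domain_dataset, desk_config):
    """HVG counts and trained latent features X0 for the shared dataset."""
    from spotfuse.expr_ae import select_hvg, train_expr_ae

    ds, truth = two_domain_dataset
    hvg, idx = select_hvg(ds.counts, 80, ds.gene_ids)
    x0, losses = train_expr_ae(hvg, desk_config, seed=0)
    return {"hvg": hvg, "hvg_idx": idx, "x0": x0, "losses": losses}


@pytest.fixture(scope="session")
def slg_graph(two_domain_dataset, expr_features, desk_config):
    from spotfuse.graphs import build_view_graph

    ds, _ = two_domain_dataset
    return build_view_graph("SLG", expr_features["x0"], ds.coords, desk_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
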