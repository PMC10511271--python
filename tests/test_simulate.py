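"""Generator contracts: determinism, planted signal, calibration, batch shifts."""

import numpy as np
import pytest
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from spotfuse.simulate import plant_dark_genes, simulate_multislice, simulate_srt


def test_same_seed_bit_identical():
    a, ta = simulate_srt(n_spots=60, n_genes=30, k_domains=2, seed=5)
    b, tb = simulate_srt(n_spots=60, n_genes=30, k_domains=2, seed=5)
    np.testing.assert_array_equal(a.counts, b.counts)
    np.testing.assert_array_equal(a.coords, b.coords)
    np.testing.assert_array_equal(a.patches, b.patches)
    np.testing.assert_array_equal(ta.domain_of_spot, tb.domain_of_spot)


def test_counts_nonnegative_integers_and_domains_contiguous():
    ds, truth = simulate_srt(n_spots=120, n_genes=40, k_domains=3, seed=2)
    assert np.all(ds.counts >= 0)
    assert ds.counts.dtype.kind in "iu"
    assert np.min(np.bincount(truth.domain_of_spot)) >= 3
    # contiguity: each spot's nearest neighbor is mostly in the same domain
    d = np.linalg.norm(ds.coords[:, None] - ds.coords[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    same = (truth.domain_of_spot[nn] == truth.domain_of_spot).mean()
    assert same > 0.8


def test_svg_genes_differ_between_domains():
    ds, truth = simulate_srt(
        n_spots=400, n_genes=100, k_domains=2, nb_mean_shift=4.0, seed=0
    )
    g = truth.svg_genes[0]
    dom = truth.domain_of_spot
    p = ranksums(ds.counts[dom == 0, g], ds.counts[dom == 1, g]).pvalue
    assert p < 1e-6


def test_zero_shift_gives_null_clustering():
    """With no domain-informative gene, expression clustering cannot recover
    the spatial domains (permutation-null behavior)."""
    aris = []
    for seed in range(10):
        ds, truth = simulate_srt(
            n_spots=150, n_genes=60, k_domains=2, nb_mean_shift=0.0, seed=seed,
            with_patches=False,
        )
        x = np.log1p(ds.counts / np.maximum(ds.counts.sum(1, keepdims=True), 1) * 1e3)
        lab = KMeans(2, n_init=10, random_state=0).fit_predict(x)
        aris.append(adjusted_rand_score(truth.domain_of_spot, lab))
    assert np.mean(np.abs(aris)) < 0.1


@pytest.fixture(scope="module")
def planted():
    ds, truth = simulate_srt(
        n_spots=400, n_genes=200, k_domains=2, nb_mean_shift=4.0, seed=0,
        with_patches=False,
    )
    return plant_dark_genes(ds, truth, n_sdg=20, spatial_amplitude=0.5,
                            noise_sd=5.0, seed=0)


def test_planting_deterministic(planted):
    ds0, truth0 = simulate_srt(
        n_spots=400, n_genes=200, k_domains=2, nb_mean_shift=4.0, seed=0,
        with_patches=False,
    )
    again, t2 = plant_dark_genes(ds0, truth0, n_sdg=20, spatial_amplitude=0.5,
                                 noise_sd=5.0, seed=0)
    np.testing.assert_array_equal(planted[0].counts, again.counts)
    np.testing.assert_array_equal(planted[1].sdg_genes, t2.sdg_genes)


def test_planted_disjoint_from_svg_and_raw_masked(planted):
    ds, truth = planted
    assert not set(truth.sdg_genes) & set(truth.svg_genes)
    ps = []
    for g in truth.sdg_genes:
        up = truth.domain_of_spot == truth.sdg_domain[int(g)]
        ps.append(ranksums(ds.counts[up, g], ds.counts[~up, g]).pvalue)
    # raw-level contrast stays weak: most planted genes are not significant
    assert np.median(ps) > 0.05
    assert np.mean(np.array(ps) < 0.01) < 0.3


def test_oracle_spatial_average_separates_planted():
    """15-NN averaging over true coordinates recovers the signal that raw
    per-spot testing misses, for most planted genes at BH FDR 0.05."""
    import warnings

    from statsmodels.stats.multitest import multipletests

    def recovery(seed):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds, truth = simulate_srt(
                n_spots=400, n_genes=200, k_domains=2, nb_mean_shift=4.0,
                seed=seed, with_patches=False,
            )
            ds, truth = plant_dark_genes(
                ds, truth, n_sdg=20, spatial_amplitude=0.5, noise_sd=5.0,
                seed=seed,
            )
        d = np.linalg.norm(ds.coords[:, None] - ds.coords[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nbrs = np.argsort(d, axis=1)[:, :15]
        spe = ds.counts[nbrs].mean(axis=1)
        fracs = []
        for mat in (spe, ds.counts):
            ps = []
            for g in truth.sdg_genes:
                up = truth.domain_of_spot == truth.sdg_domain[int(g)]
                ps.append(ranksums(mat[up, g], mat[~up, g]).pvalue)
            fracs.append(multipletests(ps, alpha=0.05, method="fdr_bh")[0].mean())
        return fracs

    got = np.array([recovery(seed) for seed in range(5)])
    spe_mean, raw_mean = got.mean(axis=0)
    assert spe_mean >= 0.6
    assert raw_mean <= 0.2
    assert spe_mean >= raw_mean + 0.4


def test_zero_amplitude_plants_nulls():
    ds, truth = simulate_srt(n_spots=200, n_genes=100, k_domains=2, seed=4,
                             with_patches=False)
    ds2, truth2 = plant_dark_genes(ds, truth, n_sdg=10, spatial_amplitude=0.0,
                                   noise_sd=5.0, seed=4)
    ps = []
    for g in truth2.sdg_genes:
        up = truth2.domain_of_spot == truth2.sdg_domain[int(g)]
        ps.append(ranksums(ds2.counts[up, g], ds2.counts[~up, g]).pvalue)
    assert np.median(ps) > 0.2  # pure noise


def test_multislice_batch_shift_and_determinism():
    ds, truth = simulate_multislice(
        dict(n_spots=100, n_genes=60), n_slices=3, batch_shift_sd=1.0, seed=0
    )
    assert ds.coords.shape[1] == 3
    assert len(set(ds.slice_id)) == 3
    lib = [ds.counts[ds.slice_id == s].mean() for s in range(3)]
    ratios = [max(a, b) / min(a, b) for a in lib for b in lib]
    assert max(ratios) > 1.5
    ds2, _ = simulate_multislice(
        dict(n_spots=100, n_genes=60), n_slices=3, batch_shift_sd=1.0, seed=0
    )
    np.testing.assert_array_equal(ds.counts, ds2.counts)


def test_multislice_no_shift_slices_exchangeable():
    ds, truth = simulate_multislice(
        dict(n_spots=100, n_genes=60), n_slices=3, batch_shift_sd=0.0, seed=1
    )
    assert truth.batch_shift is not None and np.allclose(truth.batch_shift, 0)
    lib = [ds.counts[ds.slice_id == s].mean() for s in range(3)]
    assert max(lib) / min(lib) < 1.15
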