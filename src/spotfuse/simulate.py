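"""Synthetic SRT datasets with known ground truth.

The generator emulates the features the pipeline consumes: spots on a
jittered grid whose spatial domains are contiguous Voronoi regions; negative
binomial counts whose means carry a domain fold-change on a designated SVG
subset; solid-color-plus-noise histology tiles keyed to domain; consecutive
slices sharing geometry but offset by a per-slice log-mean batch shift; and
planted "dark" genes whose smooth domain-linked mean offset is buried under
per-spot noise so that only a spatially averaged signal separates domains.

Generation is a pure function of (parameters, seed): the same call twice is
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ranksums

from .data import SpotDataset

_PALETTE = np.array(
    [
        [200, 60, 60],
        [60, 120, 200],
        [80, 180, 90],
        [220, 180, 60],
        [150, 80, 190],
        [80, 190, 190],
        [230, 120, 40],
        [120, 120, 120],
    ],
    dtype=float,
)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    domain_of_spot: np.ndarray
    svg_genes: np.ndarray
    sdg_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sdg_domain: dict = field(default_factory=dict)  # planted gene -> its up-domain
    batch_shift: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _grid_coords(n_spots: int, spacing: float, jitter: float, rng) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([xs.ravel(), ys.ravel()])[:n_spots] * spacing
    return pts + rng.uniform(-jitter, jitter, size=pts.shape)


def _voronoi_domains(coords, k, rng, min_sep, max_attempts=100):
    for _ in range(max_attempts):
        seeds = coords[rng.choice(len(coords), size=k, replace=False)]
        d = np.linalg.norm(seeds[:, None] - seeds[None], axis=-1)
        if np.min(d[np.triu_indices(k, 1)]) > min_sep:
            dist = np.linalg.norm(coords[:, None] - seeds[None], axis=-1)
            dom = dist.argmin(axis=1)
            if np.min(np.bincount(dom, minlength=k)) >= max(3, len(coords) // (5 * k)):
                return dom
    raise RuntimeError("could not place well-separated domain seeds")


def _nb_draw(rng, mean, theta):
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _simulate_means(n_spots, n_genes, domains, k, nb_mean_shift, svg_frac, rng):
    """Per-spot x per-gene NB means with a domain fold-change on SVG genes."""
    base = rng.gamma(shape=2.0, scale=1.5, size=n_genes)  # per-gene base mean
    n_svg = max(1, int(round(svg_frac * n_genes)))
    svg = np.sort(rng.choice(n_genes, size=n_svg, replace=False))
    up_domain = rng.integers(0, k, size=n_svg)
    fold = nb_mean_shift if nb_mean_shift > 0 else 1.0
    mult = np.ones((n_spots, n_genes))
    for g, d in zip(svg, up_domain):
        mult[domains == d, g] = fold
    size_factor = np.exp(rng.normal(0.0, 0.25, size=n_spots))
    return base[None, :] * mult * size_factor[:, None], svg


def _domain_patches(domains, k, patch_px, rng):
    colors = _PALETTE[np.arange(k) % len(_PALETTE)]
    noise = rng.normal(0.0, 18.0, size=(len(domains), patch_px, patch_px, 3))
    tiles = colors[domains][:, None, None, :] + noise
    return np.clip(tiles, 0, 255).astype(np.uint8)


def simulate_srt(
    n_spots: int = 400,
    n_genes: int = 200,
    k_domains: int = 2,
    nb_mean_shift: float = 4.0,
    nb_dispersion: float = 10.0,
    seed: int = 0,
    svg_frac: float = 0.25,
    spacing: float = 100.0,
    jitter: float = 10.0,
    patch_px: int = 32,
    with_patches: bool = True,
):
    """Simulate one slice: jittered grid, Voronoi domains, NB counts, tiles.

    nb_mean_shift is the fold-change applied to an SVG gene's mean inside its
    up-domain (0 disables the shift entirely, making no gene informative).
    """
    if k_domains < 2:
        raise ValueError("k_domains must be >= 2")
    if n_spots < 10 * k_domains:
        raise ValueError("need n_spots >= 10 * k_domains")
    rng = np.random.default_rng(seed)
    coords = _grid_coords(n_spots, spacing, jitter, rng)
    side = np.sqrt(n_spots) * spacing
    domains = _voronoi_domains(coords, k_domains, rng, min_sep=side / max(2, k_domains))
    means, svg = _simulate_means(
        n_spots, n_genes, domains, k_domains, nb_mean_shift, svg_frac, rng
    )
    counts = _nb_draw(rng, means, nb_dispersion)
    patches = _domain_patches(domains, k_domains, patch_px, rng) if with_patches else None
    ds = SpotDataset(
        spot_ids=[f"spot{i:05d}" for i in range(n_spots)],
        counts=counts,
        gene_ids=[f"gene{j:04d}" for j in range(n_genes)],
        coords=coords,
        labels=np.array([f"domain{d}" for d in domains], dtype=object),
        patches=patches,
    )
    truth = SimTruth(
        domain_of_spot=domains,
        svg_genes=svg,
        params=dict(
            n_spots=n_spots, n_genes=n_genes, k_domains=k_domains,
            nb_mean_shift=nb_mean_shift, nb_dispersion=nb_dispersion,
            svg_frac=svg_frac, spacing=spacing, jitter=jitter, seed=seed,
        ),
    )
    return ds, truth


def plant_dark_genes(
    dataset: SpotDataset,
    truth: SimTruth,
    n_sdg: int = 20,
    spatial_amplitude: float = 0.5,
    noise_sd: float = 5.0,
    seed: int = 0,
    base_level: float = 10.0,
):
    """Overwrite a non-SVG gene subset with a masked domain signal.

    Each planted gene gets a mean offset of `spatial_amplitude` in one domain,
    then iid per-spot noise of sd `noise_sd` (>> amplitude) before
    re-quantization to counts — so the raw one-vs-rest contrast is
    non-significant while a k-NN spatial average of the underlying mean still
    separates domains.  Returns a new (dataset, truth) pair.
    """
    if n_sdg > dataset.n_genes // 10:
        raise ValueError("n_sdg must be <= n_genes / 10")
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(dataset.n_genes), truth.svg_genes)
    planted = np.sort(rng.choice(pool, size=n_sdg, replace=False))
    k = truth.domain_of_spot.max() + 1
    counts = dataset.counts.copy().astype(float)
    sdg_domain = {}
    pvals = []
    for g in planted:
        d = int(rng.integers(0, k))
        sdg_domain[int(g)] = d
        up = truth.domain_of_spot == d
        value = (
            base_level
            + spatial_amplitude * up
            + rng.normal(0.0, noise_sd, size=dataset.n_spots)
        )
        counts[:, g] = np.round(np.clip(value, 0, None))
        if spatial_amplitude > 0:
            pvals.append(ranksums(counts[up, g], counts[~up, g]).pvalue)
    if pvals and np.median(pvals) <= 0.2:
        warnings.warn(
            f"planted dark genes may be visible in raw counts "
            f"(median raw rank-sum p = {np.median(pvals):.3f})"
        )
    new_ds = SpotDataset(
        spot_ids=dataset.spot_ids,
        counts=counts.astype(int),
        gene_ids=dataset.gene_ids,
        coords=dataset.coords,
        labels=dataset.labels,
        patches=dataset.patches,
        slice_id=dataset.slice_id,
    )
    new_truth = SimTruth(
        domain_of_spot=truth.domain_of_spot,
        svg_genes=truth.svg_genes,
        sdg_genes=planted,
        sdg_domain=sdg_domain,
        batch_shift=truth.batch_shift,
        params={
            **truth.params,
            "n_sdg": n_sdg,
            "spatial_amplitude": spatial_amplitude,
            "noise_sd": noise_sd,
            "sdg_base_level": base_level,
            "sdg_seed": seed,
        },
    )
    return new_ds, new_truth


def simulate_multislice(
    base_config: dict | None = None,
    n_slices: int = 3,
    batch_shift_sd: float = 1.0,
    z_gap: float = 100.0,
    seed: int = 0,
):
    """Consecutive slices sharing domain geometry, with additive batch shifts.

    Every slice reuses the slice-0 spot layout and per-spot/per-gene NB means;
    slice s multiplies all means by exp(shift_s) with shift_s ~ N(0,
    batch_shift_sd).  z = slice_index * z_gap.  Patches are omitted
    (emulating bead-array platforms without histology).
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    cfg = dict(
        n_spots=150, n_genes=120, k_domains=2, nb_mean_shift=4.0,
        nb_dispersion=10.0, svg_frac=0.25, spacing=100.0, jitter=10.0,
    )
    cfg.update(base_config or {})
    rng = np.random.default_rng(seed)
    coords2d = _grid_coords(cfg["n_spots"], cfg["spacing"], cfg["jitter"], rng)
    side = np.sqrt(cfg["n_spots"]) * cfg["spacing"]
    domains = _voronoi_domains(
        coords2d, cfg["k_domains"], rng, min_sep=side / max(2, cfg["k_domains"])
    )
    means, svg = _simulate_means(
        cfg["n_spots"], cfg["n_genes"], domains, cfg["k_domains"],
        cfg["nb_mean_shift"], cfg["svg_frac"], rng,
    )
    shifts = rng.normal(0.0, batch_shift_sd, size=n_slices)
    ids, rows, coords3d, slice_id = [], [], [], []
    for s in range(n_slices):
        rows.append(_nb_draw(rng, means * np.exp(shifts[s]), cfg["nb_dispersion"]))
        ids.extend(f"s{s}_spot{i:05d}" for i in range(cfg["n_spots"]))
        coords3d.append(
            np.column_stack([coords2d, np.full(cfg["n_spots"], s * z_gap)])
        )
        slice_id.extend([s] * cfg["n_spots"])
    all_domains = np.tile(domains, n_slices)
    ds = SpotDataset(
        spot_ids=ids,
        counts=np.vstack(rows),
        gene_ids=[f"gene{j:04d}" for j in range(cfg["n_genes"])],
        coords=np.vstack(coords3d),
        labels=np.array([f"domain{d}" for d in all_domains], dtype=object),
        slice_id=np.array(slice_id),
    )
    truth = SimTruth(
        domain_of_spot=all_domains,
        svg_genes=svg,
        batch_shift=shifts,
        params={**cfg, "n_slices": n_slices, "batch_shift_sd": batch_shift_sd,
                "z_gap": z_gap, "seed": seed},
    )
    return ds, truth
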