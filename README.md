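# spotfuse

Multiview graph-attention fusion for spatially resolved transcriptomics
(SRT). `spotfuse` integrates four information sources available for a tissue
section — gene expression, histology image patches, spatial location, and
gene–gene association — into one low-dimensional embedding per spot, and uses
that embedding for:

* **spatial-domain detection** (k-means with Davies–Bouldin model selection),
* **expression denoising** via spatial pseudo-expression (SPE): each spot's
  counts replaced by the mean over its 15 nearest embedding neighbors,
* **3-D domain detection** across consecutive slices, mitigating slice batch
  effects through cross-slice graph edges,
* **spatial dark gene (SDG) discovery**: genes differential in SPE but *not*
  in raw expression — spatially organized signal that per-spot testing misses.

It is aimed at computational biologists analyzing Visium / Slide-seq /
STARmap-style data who want a supervisable, multi-view alternative to
single-view graph embeddings, plus a fully synthetic test bed with known
ground truth.

## Model

**Per-spot features.** Expression features `X0` come from an autoencoder with
a negative-binomial reconstruction likelihood
`NB(x; u, θ)` — encoder `[G, 1000, 50]`, decoder heads for the mean
(softmax proportions scaled by the spot's library size) and dispersion
(softplus). Visual features `v` come from contrastive pretraining of a small
convolutional encoder (two augmented views per patch, NT-Xent loss, optional
label fine-tuning and teacher–student distillation).

**View graphs.** Three symmetric kNN graphs over spots, each with a P-channel
positive edge-feature vector:

| view | neighbors by | edge features |
|------|--------------|---------------|
| HSG  | cosine of `v` | cos(v_i, v_j), exp(−‖v_i−v_j‖), Pearson(v_i, v_j) |
| SLG  | Euclidean of coords | (s_i·s_j)/‖s_i−s_j‖, [dist ≤ λ], [\|Δy\| ≤ μ] (+ [\|Δz\| ≤ ξ] in 3-D) |
| GAG  | cosine of `X0` | same similarity triple on `X0`; node features are the autoencoded conditional degree matrix |

The conditional degree matrix counts, per cell, each gene's partners in a
cell-specific conditional-independence network: for genes x, y given a hub
conditioning gene z, `ρ = n_xyz/n_z − (n_xz/n_z)(n_yz/n_z)` over expression
neighborhoods, thresholded at level α.

**EGAT encoder.** Each layer computes attention
`f_ij = exp(LeakyReLU(aᵀ[Wx_i ∥ Wx_j]))`, modulates it channel-wise by the
edge features, normalizes every channel to a symmetric doubly stochastic
matrix, aggregates `Wx` per channel and concatenates; the attention tensor
becomes the next layer's edge features. Training minimizes
`L = BCE(A, sigmoid(RRᵀ)) + 8 · CE(Y, softmax(head(R)))` with weak labels on
a fraction of spots.

**Fusion.** Per-view embeddings are projected to a common width, stacked as
channels, gated by channel attention (MLP over the view axis) then spatial
attention (two convolutions over the spot × latent plane), and summed over
views: `R = F3[1] + F3[2] + F3[3]`.

## Worked example

```bash
python examples/01_domains_from_simulated_tissue.py
```

```
views used          : ['GAG', 'SLG']
fused embedding     : (300, 32)
ARI vs planted truth: 1.000
ASW of clustering   : 0.748
```

Three hundred simulated spots with two contiguous domains and a 4-fold SVG
shift: the fused embedding recovers the planted domains exactly (ARI 1.0)
with a wide silhouette margin. The other examples demonstrate dark-gene
discovery (`02`), 3-D batch-effect mitigation (`03` — on a 3-slice fixture
with log-scale shifts `[1.9, 0.39, 0.31]` the 2-D pipeline reaches ARI 0.393
while the 3-D pipeline reaches 1.000), and the view graphs (`04`).

The same pipeline is available as a CLI:

```bash
spotfuse simulate --outdir data --n-spots 300 --seed 1
spotfuse run --data data --outdir out --use-labels --seed 0
```

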