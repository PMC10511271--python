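# Methods

This note documents the models implemented in `spotfuse`, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and the limits of what those tests show.

## Expression features: negative-binomial autoencoder

Counts for spot i, gene g are modeled as `x_ig ~ NB(u_ig, θ_ig)` in the
mean/dispersion parameterization. A fully connected encoder
(`[G, hidden, latent]`, batch-norm + ReLU + dropout) maps library-normalized
log counts to a latent `z_i`; the decoder mirrors it and emits two heads:

* **mean**: softmax over genes, interpreted as per-gene proportions, scaled
  by the spot's total count. A softmax head cannot represent unconstrained
  positive means directly, so the library scaling carries the magnitude;
  a plain softplus head is available via `ae_mean_head="softplus"`.
* **dispersion**: softplus (+1e-4), strictly positive.

The loss is the mean NB negative log-likelihood, computed with log-gamma
arithmetic. The encoder is deterministic: the training objective is a plain
reconstruction likelihood with no sampling or KL term.

Published operating point: widths `[2000, 1000, 50]`, Adam with lr 8e-5 and
weight decay 1e-6. Those remain the `RunConfig` defaults. At the package's
desk scale (hundreds of spots, ≤ 200 genes, full-batch training for tens of
epochs) an 8e-5 step size cannot move the loss measurably, so the fixture
protocol used throughout the tests and examples is lr 1e-3, hidden width 128,
60 epochs; widths are additionally capped at `4 × n_genes`. Size factors are
per-spot totals; a spot with zero total gets factor 1.

**HVG selection** scores each gene by the variance of its log1p
library-normalized counts (a log-scale dispersion measure that is nearly
flat in expression level for overdispersed counts), keeps the top `n_top`,
breaks ties by gene id, and ranks constant genes last.

## Visual features: contrastive patch encoder

A four-block stride-2 convolutional encoder (widths 8/16/32/64, ELU, global
average pooling) with a three-layer projection head is pretrained with the
NT-Xent loss on two stochastic augmentations per patch (crop to 50–100% and
resize, brightness ±0.2 / contrast 0.8–1.2 jitter, Gaussian blur σ ∈ [0, 1]).
With labels, a classifier is fine-tuned from the *first* projection layer
(the retained half of the head) and the mid-projection output becomes the
per-spot feature; otherwise the encoder output is used. A distillation path
(`train_distilled_student`) trains a two-block student against softened
teacher probabilities with the cross-entropy `−Σ P_T log P_S`.

## View graphs

All views share one edge-selection rule — symmetric kNN (default 6) under
the view's natural metric, deterministic index tie-break — because the
underlying similarity formulas define edge *features*, not an edge *set*.

Positivity of edge features (required by the doubly stochastic attention) is
obtained per channel: bounded channels (cosine, Pearson) by `f → (f+1)/2 + ε`;
binary indicators by `+ε`; the unbounded SLG dot/distance channel is first
scaled by its maximum absolute value over the edge set. ε = 1e-6. The
pre-shift values are stored alongside.

The SLG `|Δy| ≤ μ` indicator uses the ≤ direction (`mu_rule="le"`); the
opposite convention exists in the literature and is available as a flag.
Defaults λ = 200, μ = 10 are in the coordinate file's units; ξ (3-D) defaults
to the smallest inter-slice z gap so that exactly adjacent slices connect.

**Conditional gene association.** For genes x, y given conditioning gene z in
cell k, neighborhoods are per-gene windows `[max(0, x_k − h), x_k + h]` with
half-width `h = boxsize · sd(gene)/2` (boxsize 1.5), and
`ρ = n_xyz/n_z − (n_xz/n_z)(n_yz/n_z)`. ρ is standardized by its
independence-null sd `sqrt(p_x(1−p_x) p_y(1−p_y)/n_z)` and an edge requires
the standardized statistic to exceed the normal quantile at level α
(α = 0.5 ⇒ positive association). Conditioning genes default to the `kk`
hubs of an unconditional pass of the same statistic; pairs involving a
conditioning gene are excluded, so its own degree is 0. The per-cell degree
sums form the genes × cells conditional degree matrix, which is reduced by
the same autoencoder to per-cell node features for the GAG. To bound the
O(m²·n²) cost the association network is restricted to the top `gag_genes`
(default 60) HVGs.

## EGAT

Doubly stochastic normalization per channel is the closed form
`T = rownorm(A)`, `E = T (T / colsum(T))ᵀ`, which is symmetric with unit row
sums whenever every node has support. (The two-stage denominator uses the
row-normalized matrix; using raw features there would break both symmetry
and stochasticity.) Attention scores are shifted by their detached row
maximum before exponentiation — an exact invariance of the normalization,
used only to avoid overflow.

Layers: 2, widths 128 then 32 per channel, ELU, LeakyReLU slope 0.2; the
per-view embedding is the concatenation over the P channels of the final
layer (width `P × 32`). Loss = adjacency BCE from logits over all n² pairs
plus 8× the cross-entropy of a linear softmax head on the labeled spots
(the head keeps the latent width free of the class count; with no labels the
model trains on reconstruction alone). Adam lr 1e-3, 80 epochs default
(40 in the fixture protocol). The dense implementation holds n × n × P
tensors, appropriate for desk-scale n; all computations are pure functions
of the seed.

## Global attention fusion

Views are projected to width 32 and stacked as channels of `F1 ∈ R^{C×H×W}`
(H = spots, W = latent). Channel attention applies a 2-layer MLP with
reduction ratio γ = 4 (hidden floored at 1, since C is 2–3) across the
channel axis at every (spot, latent) position; spatial attention applies a
channel-reducing (7, 1) convolution then a channel-restoring (1, 7)
convolution over the (spot, latent) plane. Both gates are sigmoids,
multiplied elementwise. `R` is the channel sum of the gated stack. Because
the spot axis has no raster meaning, the convolution sees spots in input
order; this is an acknowledged arbitrariness of applying image-style spatial
attention to an unordered axis, and the kernels are deliberately separable
and small. Training (when labels exist) minimizes cross-entropy of a linear
head on labeled spots; without labels the deterministically initialized
gates are applied untrained.

## Downstream

* **Clustering**: k-means (10 restarts, seeded), cluster ids renumbered by
  descending size; when k is unknown it is chosen by the smallest
  Davies–Bouldin index over `k_range` (ties → smaller k).
* **SPE**: per spot, the mean of the raw count rows of its `spe_k = 15`
  nearest neighbors by Euclidean distance in embedding space, self excluded
  (configurable), ties by index.
* **SVG/SPVG/SDG**: per gene and cluster, one-vs-rest Wilcoxon rank-sum on
  raw counts and on SPE, BH correction within each modality across all
  gene × cluster tests. SVG: some cluster with `q_raw < fdr` and
  `|log2FC_raw| ≥ lfc_min`; SPVG analogously on SPE; SDG = SPE-differential
  and not raw-differential. The gene-level class is SDG, else SPVG (both
  modalities), else SVG (raw only), else none. Defaults fdr 0.05,
  lfc_min 0.25. For *dark-gene* protocols lfc_min is set to 0: a planted
  offset of half a count on a base of ~10 is a real spatial signal with
  |log2FC| ≈ 0.07, so any fold-change filter would veto every dark gene by
  construction; the fold-change filter is meant for marker-style contrasts.
* A caveat the tests quantify: rank-sum p-values on SPE are
  anti-conservative, because k-NN averaging makes neighboring spots share
  observations (the null z inflates by roughly √k). SDG calls should be read
  as a screening ranking, not as calibrated per-gene inference.

## 2-D vs 3-D multi-slice mode

With a slice index present, 2-D mode restricts SLG neighbor search to
within-slice pairs (each slice keeps its own spatial graph); 3-D mode runs
kNN in (x, y, z) and adds the fourth edge channel `[|Δz| ≤ ξ]`, so adjacent
slices acquire edges and attention can average expression across them. The
packaged 2-D/3-D comparison runs label-free: weak supervision with
ground-truth domain labels would align slices through the classifier head
and mask the graph-structural effect being measured.

## Synthetic data

`simulate_srt` emulates: spots on a jittered grid (spacing 100, jitter 10 —
units chosen so the default λ/μ thresholds are meaningful); contiguous
domains as Voronoi cells of well-separated seeds (each domain ≥ n/(5k)
spots); NB counts with gamma(2, 1.5) per-gene base means, log-normal
(sd 0.25) spot size factors, dispersion θ = 10 (BCV ≈ 0.32, the
realistic range for UMI data; markedly noisier settings make 4-fold shifts
statistically invisible at desk scale); a designated SVG subset (25%
default) with a domain fold-change; solid domain color + pixel-noise tiles
as histology. `simulate_multislice` replicates one slice geometry with
per-slice multiplicative `exp(N(0, sd))` batch shifts and `z = slice · gap`.
`plant_dark_genes` overwrites non-SVG genes with
`round(clip(base + amplitude·[domain] + N(0, noise_sd)))` (base 10,
amplitude 0.5, noise 5) and verifies at generation time that the raw
contrast stays non-significant (median rank-sum p > 0.2, else a warning).

What it does **not** emulate: H&E texture, cell-type mixtures within spots,
zero inflation beyond NB, segmentation noise, spatial gradients within a
domain, or library-depth gradients. Passing tests therefore demonstrate the
machinery and its contracts, not performance on real tissue.

A note on attainable dark-gene sensitivity: with amplitude 0.5, noise sd 5
and 400 spots, each planted gene carries a total signal of
z = 0.5/(5·√(2/200)) = 1.0, so sensitivity/false-positive trade-offs are
capped (ROC d′ ≈ 1) no matter the estimator; measured 5-seed sensitivity of
the caller under an idealized embedding is ~0.6–0.7.

## Numerical choices

* float64 throughout; Adam (β = 0.9/0.999, ε = 1e-8), deterministic
  parameter order; all RNG through seeded `numpy.random.Generator`s.
* BCE is computed from logits (`softplus`) during training and from clipped
  probabilities (1e-7) in the closed-form API.
* DS normalization guards empty rows/columns with masked denominators and
  raises on isolated nodes.
* kNN and SPE neighbor ranking use `lexsort` on (index, distance) for exact
  tie determinism; k-means uses a fixed `random_state` with 10 restarts.
* Problem sizes in tests and the acceptance script (300–400 spots, 100–200
  genes, 3 × 120-spot slices, 40–60 training epochs) were chosen as the
  smallest sizes at which the statistical claims are testable.

## Known limitations

* The dense EGAT implementation is O(n²P) memory; thousands of spots fit,
  hundreds of thousands will not — a sparse backend would be needed.
* Fusion without labels applies untrained attention gates; the published
  method assumes weak supervision for the fusion stage.
* DBI-based model selection inherits k-means' convexity bias and can merge
  thin, curved domains.
* SPE p-values are anti-conservative (see above); SDG output is a ranking.
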