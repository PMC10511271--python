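"""Detect spatial domains on a simulated two-domain tissue.

Simulates 300 spots with negative-binomial counts whose SVG subset carries a
4-fold change between two contiguous domains, runs the full pipeline
(expression autoencoder -> SLG + GAG view graphs -> EGAT -> attention fusion
-> k-means), and compares the detected domains with the planted truth.
"""

import dataclasses

from spotfuse import RunConfig, simulate_srt
from spotfuse.downstream import ari, asw, run_pipeline

ds, truth = simulate_srt(
    n_spots=300, n_genes=100, k_domains=2, nb_mean_shift=4.0, seed=1,
    with_patches=False,
)
cfg = dataclasses.replace(
    RunConfig(), ae_lr=1e-3, ae_epochs=60, ae_hidden=128, egat_epochs=40,
    gag_genes=50, cluster_k=2, seed=0,
)
result = run_pipeline(ds, cfg)

print(f"views used          : {result.manifest['views']}")
print(f"fused embedding     : {result.fused.shape}")
print(f"ARI vs planted truth: {ari(truth.domain_of_spot, result.clusters):.3f}")
print(f"ASW of clustering   : {asw(result.fused, result.clusters):.3f}")
# ARI = 1 means the two planted domains are recovered exactly; ASW > 0.5
# says the fused embedding separates them with a wide margin.
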