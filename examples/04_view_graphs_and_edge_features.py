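"""Inspect the three view graphs and their multidimensional edge features.

Builds the spatial-location graph (SLG), the gene-association graph (GAG)
and the histology-similarity graph (HSG) for a small simulated tissue and
prints one edge's feature channels per view.
"""

import dataclasses

from spotfuse import RunConfig, simulate_srt
from spotfuse.expr_ae import select_hvg, train_expr_ae
from spotfuse.graphs import build_view_graph, conditional_degree_matrix
from spotfuse.visual import train_contrastive

ds, truth = simulate_srt(n_spots=64, n_genes=60, k_domains=2, seed=2)
cfg = dataclasses.replace(
    RunConfig(), ae_lr=1e-3, ae_epochs=30, ae_hidden=64, simclr_epochs=4,
    simclr_batch=32, gag_genes=30,
)

hvg, _ = select_hvg(ds.counts, 40, ds.gene_ids)
x0, _ = train_expr_ae(hvg, cfg, seed=0)

slg = build_view_graph("SLG", x0, ds.coords, cfg)
cdm = conditional_degree_matrix(hvg[:, :30], kk=1)
v_embed, _ = train_expr_ae(cdm.degrees.T, cfg, seed=1)
gag = build_view_graph("GAG", v_embed, x0, cfg)
v, _ = train_contrastive(ds.patches, cfg, seed=0)
hsg = build_view_graph("HSG", x0, v, cfg)

print(f"conditional degree matrix: {cdm.degrees.shape} "
      f"(hub gene index {cdm.conditioning_genes})")
for g in (slg, gag, hsg):
    i, j = g.edges[0]
    print(f"{g.view_name}: {len(g.edges) // 2} undirected edges; "
          f"edge ({i},{j}) raw features {g.raw_edge_features[0].round(3)}")
# SLG channels: planar dot/distance, [distance <= lambda], [|dy| <= mu];
# GAG/HSG channels: cosine, exp(-L2 distance), Pearson of the aux features.
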