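"""Run configuration: every tunable of the pipeline with its default.

Defaults mirror the method's published operating point where one exists
(autoencoder architecture and optimizer, SLG thresholds mu/lambda, the
conditional-network parameters, the 15-neighbor pseudo-expression) and
desk-scale choices elsewhere (documented in docs/methods.md).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    # expression autoencoder
    hvg_count: int = 2000
    ae_latent: int = 50
    ae_hidden: int = 1000
    ae_lr: float = 8e-5
    ae_weight_decay: float = 1e-6
    ae_epochs: int = 200
    ae_dropout: float = 0.1
    ae_mean_head: str = "softmax"  # "softmax" (proportions x library) or "softplus"

    # contrastive visual features
    simclr_tau: float = 0.5
    simclr_epochs: int = 20
    simclr_batch: int = 64
    simclr_lr: float = 1e-3
    visual_dim: int = 64
    patch_px: int = 32

    # spatial-location graph thresholds (same units as the coordinate file)
    slg_lambda: float = 200.0
    slg_mu: float = 10.0
    slg_xi: float | None = None  # 3D z threshold; None -> smallest inter-slice gap
    mu_rule: str = "le"  # e3 = 1 when |dy| <= mu ("le") or > mu ("gt")

    # graph construction
    knn_edges: int = 6
    edge_eps: float = 1e-6

    # conditional cell-specific gene-association network
    ccsn_alpha: float = 0.5
    ccsn_boxsize: float = 1.5
    ccsn_kk: int = 1
    gag_genes: int = 60  # HVG subset used for the association network

    # EGAT
    egat_hidden: int = 128
    egat_out: int = 32
    egat_loss_weight: float = 8.0
    egat_lr: float = 1e-3
    egat_epochs: int = 80
    leaky_slope: float = 0.2

    # global attention fusion
    gam_reduction: int = 4
    gam_width: int = 32
    gam_kernel: int = 7
    gam_lr: float = 1e-3
    gam_epochs: int = 60

    # downstream
    spe_k: int = 15
    cluster_k: int | None = None
    k_range: tuple = (2, 8)  # inclusive bounds scanned when cluster_k is None
    fdr: float = 0.05
    lfc_min: float = 0.25
    label_frac: float = 0.7  # fraction of labeled spots used for weak supervision

    seed: int = 0

    def __post_init__(self):
        for name in (
            "hvg_count", "ae_latent", "ae_hidden", "ae_lr", "slg_lambda",
            "slg_mu", "knn_edges", "ccsn_boxsize", "gam_reduction", "spe_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.spe_k < 1:
            raise ValueError("spe_k must be >= 1")
        if self.mu_rule not in ("le", "gt"):
            raise ValueError("mu_rule must be 'le' or 'gt'")

    # -- key: value file round-trip ---------------------------------------
    def to_file(self, path):
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path, **overrides):
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or ":" not in line:
                continue
            k, v = line.split(":", 1)
            raw[k.strip()] = v.strip()
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        int_fields = {
            "hvg_count", "ae_latent", "ae_hidden", "ae_epochs", "simclr_epochs",
            "simclr_batch", "visual_dim", "patch_px", "knn_edges", "ccsn_kk",
            "gag_genes", "egat_hidden", "egat_out", "egat_epochs",
            "gam_reduction", "gam_width", "gam_kernel", "gam_epochs", "spe_k",
            "cluster_k", "seed",
        }
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, str):
                if v == "None":
                    v = None
                elif f.name == "k_range":
                    v = tuple(int(x) for x in v.split(","))
                elif f.name in int_fields:
                    v = int(v)
                elif f.name not in ("ae_mean_head", "mu_rule"):
                    v = float(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def asdict(self):
        return asdict(self)
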