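"""spotfuse: multiview graph-attention fusion for spatially resolved transcriptomics.

The package learns one low-dimensional embedding per spot by fusing four
information sources — gene expression, histology, spatial location and
gene–gene association — and uses it for spatial-domain detection, expression
denoising via spatial pseudo-expression (SPE) and the discovery of spatial
dark genes (SDGs): genes differential in SPE but not in raw expression.
"""

__version__ = "0.1.0"

from .config import RunConfig
from .data import SpotDataset, load_expression, load_patches, load_spots
from .simulate import SimTruth, plant_dark_genes, simulate_multislice, simulate_srt

__all__ = [
    "RunConfig",
    "SpotDataset",
    "SimTruth",
    "load_expression",
    "load_spots",
    "load_patches",
    "simulate_srt",
    "plant_dark_genes",
    "simulate_multislice",
    "run_pipeline",
]


def run_pipeline(*args, **kwargs):
    """End-to-end pipeline; see :func:`spotfuse.downstream.run_pipeline`."""
    from .downstream import run_pipeline as _run

    return _run(*args, **kwargs)
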