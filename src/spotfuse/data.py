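"""Readers/writers for SRT inputs and the unified :class:`SpotDataset` object.

Expression comes in as Matrix Market (10x convention: genes x spots) or as a
dense CSV/TSV (spots in rows); the spot table is a CSV with per-spot
coordinates and optional slice index / region label; histology can be supplied
either as one tile image per spot or as a whole-slide image plus pixel
coordinates.  All loaders align everything to the expression spot order by an
id join and validate the invariants (non-negative integer counts, unique ids,
finite coordinates, uniform patch size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

log = logging.getLogger("spotfuse")

UNLABELED = "unlabeled"


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


@dataclass
class SpotDataset:
    """Counts, coordinates and optional labels / image patches for one run.

    counts is spots x genes (non-negative integers); coords is spots x 2 or 3;
    labels may cover only a subset of spots — missing entries hold the
    distinguished ``UNLABELED`` category.  patches, when present, is a uint8
    array (spots, px, px, 3).
    """

    spot_ids: list
    counts: np.ndarray
    gene_ids: list
    coords: np.ndarray | None = None
    labels: np.ndarray | None = None
    patches: np.ndarray | None = None
    slice_id: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self):
        n, g = self.counts.shape
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spot_ids)} spot ids x {len(self.gene_ids)} gene ids"
            )
        for name, ids in (("spot", self.spot_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if list(ids).count(i) > 1})[:5]
                raise FormatError(f"duplicate {name} ids: {dup}")
        if np.any(self.counts < 0):
            raise FormatError("counts contain negative entries")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise FormatError("counts contain non-integer entries")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape[0] != n or self.coords.shape[1] not in (2, 3):
                raise FormatError("coords must be spots x 2 or spots x 3")
            if not np.all(np.isfinite(self.coords)):
                raise FormatError("coords contain non-finite values")
        if self.patches is not None:
            self.patches = np.asarray(self.patches)
            if self.patches.shape[0] != n or self.patches.ndim != 4:
                raise FormatError("patches must be (spots, px, px, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != n:
                raise FormatError("labels length does not match spots")
        if self.slice_id is not None:
            self.slice_id = np.asarray(self.slice_id, dtype=int)
            if self.slice_id.shape[0] != n:
                raise FormatError("slice_id length does not match spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def label_codes(self):
        """Integer label codes (-1 for unlabeled) plus the class list."""
        if self.labels is None:
            return -np.ones(self.n_spots, dtype=int), []
        classes = sorted({l for l in self.labels if l is not None and l != UNLABELED})
        lut = {c: i for i, c in enumerate(classes)}
        codes = np.array(
            [lut.get(l, -1) if l is not None else -1 for l in self.labels], dtype=int
        )
        return codes, classes

    # -- persistence -------------------------------------------------------
    def save(self, outdir):
        """Write the dataset in the same formats the loaders read."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mat = coo_matrix(np.asarray(self.counts, dtype=int).T)  # genes x spots
        mmwrite(str(out / "matrix.mtx"), mat)
        (out / "genes.txt").write_text("\n".join(map(str, self.gene_ids)) + "\n")
        (out / "barcodes.txt").write_text("\n".join(map(str, self.spot_ids)) + "\n")
        tbl = {"id": self.spot_ids}
        if self.coords is not None:
            tbl["x"] = self.coords[:, 0]
            tbl["y"] = self.coords[:, 1]
            if self.coords.shape[1] == 3:
                tbl["z"] = self.coords[:, 2]
        if self.slice_id is not None:
            tbl["slice"] = self.slice_id
        if self.labels is not None:
            tbl["label"] = [l if l is not None else UNLABELED for l in self.labels]
        pd.DataFrame(tbl).to_csv(out / "spots.csv", index=False)
        if self.patches is not None:
            from PIL import Image

            pdir = out / "patches"
            pdir.mkdir(exist_ok=True)
            for sid, patch in zip(self.spot_ids, self.patches):
                Image.fromarray(patch).save(pdir / f"{sid}.png")

    @classmethod
    def load(cls, indir, load_images: bool = True):
        indir = Path(indir)
        ds = load_expression(
            indir / "matrix.mtx", indir / "genes.txt", indir / "barcodes.txt"
        )
        if (indir / "spots.csv").exists():
            ds = load_spots(indir / "spots.csv", ds)
        pdir = indir / "patches"
        if load_images and pdir.is_dir():
            ds = load_patches(pdir, ds)
        return ds


def _read_ids(path) -> list:
    ids = [l.strip().split("\t")[0] for l in Path(path).read_text().splitlines()]
    return [i for i in ids if i]


def load_expression(matrix_path, genes_path=None, barcodes_path=None) -> SpotDataset:
    """Load a count matrix (MTX + id files, or a dense CSV/TSV) as spots x genes.

    MTX follows the 10x convention genes x spots and is transposed; a dense
    table has spots in rows (index column) and genes in the header.  Ambiguous
    square MTX matrices are resolved as genes x spots with a warning.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx" or matrix_path.name.endswith(".mtx.gz"):
        if genes_path is None or barcodes_path is None:
            raise FormatError("MTX input requires genes and barcodes id files")
        mat = np.asarray(mmread(str(matrix_path)).todense())
        genes, spots = _read_ids(genes_path), _read_ids(barcodes_path)
        ng, ns = len(genes), len(spots)
        if mat.shape == (ng, ns):
            if ng == ns:
                log.warning(
                    "square MTX (%d x %d): assuming genes x spots", ng, ns
                )
            counts = mat.T
        elif mat.shape == (ns, ng):
            counts = mat
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither {ng} genes x "
                f"{ns} spots nor its transpose"
            )
        return SpotDataset(spot_ids=spots, counts=counts, gene_ids=genes)
    sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    return SpotDataset(
        spot_ids=[str(i) for i in df.index],
        counts=df.to_numpy(),
        gene_ids=[str(c) for c in df.columns],
    )


def load_spots(path, dataset: SpotDataset) -> SpotDataset:
    """Attach coords / labels / slice index from a spot table, joined by id.

    Row order on disk is irrelevant; every expression spot must be present.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if "id" not in df.columns or not {"x", "y"} <= set(df.columns):
        raise FormatError("spot table needs columns id, x, y")
    df = df.set_index("id")
    if df.index.duplicated().any():
        raise FormatError("duplicate ids in spot table")
    missing = [s for s in dataset.spot_ids if s not in df.index]
    if missing:
        raise FormatError(f"spots missing from coordinate table: {missing[:10]}")
    df = df.loc[[str(s) for s in dataset.spot_ids]]
    cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
    coords = df[cols].to_numpy(dtype=float)
    labels = None
    if "label" in df.columns:
        labels = np.array(
            [UNLABELED if pd.isna(l) else str(l) for l in df["label"]], dtype=object
        )
    slice_id = df["slice"].to_numpy(dtype=int) if "slice" in df.columns else None
    return SpotDataset(
        spot_ids=dataset.spot_ids,
        counts=dataset.counts,
        gene_ids=dataset.gene_ids,
        coords=coords,
        labels=labels,
        patches=dataset.patches,
        slice_id=slice_id,
    )


def crop_patch(image: np.ndarray, cx: float, cy: float, patch_px: int) -> np.ndarray:
    """Crop a patch_px square centered at pixel (cx, cy), reflect-padding edges."""
    h, w = image.shape[:2]
    half = patch_px // 2
    r0, c0 = int(round(cy)) - half, int(round(cx)) - half
    r1, c1 = r0 + patch_px, c0 + patch_px
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        warnings.warn("patch crop outside image bounds; reflect-padded")
        pad = patch_px
        image = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        r0, c0, r1, c1 = r0 + pad, c0 + pad, r1 + pad, c1 + pad
    return image[r0:r1, c0:c1]


def load_patches(
    source, dataset: SpotDataset, patch_px: int = 32, pixel_cols: np.ndarray | None = None
) -> SpotDataset:
    """Attach one RGB tile per spot.

    `source` is either a directory of per-spot tiles named ``<spot_id>.png``
    (or .tif/.tiff/.jpg), or a whole-slide image file, in which case
    `pixel_cols` gives the (x, y) pixel position of each spot (defaults to the
    dataset coordinates).
    """
    from PIL import Image

    source = Path(source)
    if source.is_dir():
        tiles = []
        for sid in dataset.spot_ids:
            hits = [
                p
                for ext in (".png", ".tif", ".tiff", ".jpg")
                if (p := source / f"{sid}{ext}").exists()
            ]
            if not hits:
                raise FormatError(f"missing image tile for spot {sid}")
            tiles.append(np.asarray(Image.open(hits[0]).convert("RGB")))
        shapes = {t.shape for t in tiles}
        if len(shapes) > 1:
            raise FormatError(f"tiles have mixed dimensions: {sorted(shapes)}")
        patches = np.stack(tiles)
    else:
        image = np.asarray(Image.open(source).convert("RGB"))
        px = pixel_cols if pixel_cols is not None else dataset.coords[:, :2]
        patches = np.stack(
            [crop_patch(image, x, y, patch_px) for x, y in np.asarray(px)]
        )
    return SpotDataset(
        spot_ids=dataset.spot_ids,
        counts=dataset.counts,
        gene_ids=dataset.gene_ids,
        coords=dataset.coords,
        labels=dataset.labels,
        patches=patches,
        slice_id=dataset.slice_id,
    )


# -- TSV helpers used across the pipeline ----------------------------------
def write_tsv_matrix(path, matrix: np.ndarray, row_ids, col_names=None):
    cols = col_names or [f"c{i}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=list(row_ids), columns=cols).to_csv(
        path, sep="\t", index_label="id", float_format="%.10g"
    )


def read_tsv_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(i) for i in df.index], list(df.columns)
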