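"""Reading and writing of on-disk formats.

Count matrices use the CellRanger-style triplet layout: ``matrix.mtx``
(MatrixMarket, genes x barcodes), ``features.tsv`` and ``barcodes.tsv``,
with barcode-level metadata in ``metadata.tsv`` and any planted ground
truth in ``truth.json``. Images are single-channel 16-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from nigra.assay import CountAssay

MATRIX = "matrix.mtx"
FEATURES = "features.tsv"
BARCODES = "barcodes.tsv"
METADATA = "metadata.tsv"
TRUTH = "truth.json"


def write_assay(assay: CountAssay, outdir: str | Path) -> Path:
    """Write an assay as an uncompressed MTX triplet plus metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / MATRIX), assay.counts.tocoo())
    assay.gene_meta.to_csv(outdir / FEATURES, sep="\t", index=False)
    meta = assay.barcode_meta.copy()
    if "barcode" not in meta.columns:
        meta.insert(0, "barcode", assay.barcode_ids)
    meta[["barcode"]].to_csv(outdir / BARCODES, sep="\t", index=False, header=False)
    meta.to_csv(outdir / METADATA, sep="\t", index=False)
    if assay.uns:
        with open(outdir / TRUTH, "w") as fh:
            json.dump(_jsonable(assay.uns), fh, indent=1)
    return outdir


def read_assay(indir: str | Path) -> CountAssay:
    """Read an assay written by :func:`write_assay`."""
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / MATRIX))
    gene_meta = pd.read_csv(indir / FEATURES, sep="\t")
    meta_path = indir / METADATA
    if meta_path.exists():
        barcode_meta = pd.read_csv(meta_path, sep="\t")
    else:
        barcodes = pd.read_csv(indir / BARCODES, sep="\t", header=None)
        barcode_meta = pd.DataFrame({"barcode": barcodes[0]})
    uns = {}
    if (indir / TRUTH).exists():
        with open(indir / TRUTH) as fh:
            uns = json.load(fh)
    return CountAssay(counts=counts, gene_meta=gene_meta, barcode_meta=barcode_meta, uns=uns)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_image(array: np.ndarray, path: str | Path) -> None:
    """Write a single-channel image as 16-bit TIFF."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
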