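"""Core container for sparse gene x barcode count data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

VALID_CONDITIONS = ("control", "case")


@dataclass
class CountAssay:
    """Sparse UMI count matrix (genes x barcodes) plus metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, barcodes in
        columns.
    gene_meta
        One row per gene. Expected columns include ``gene_id`` and the
        boolean flags ``is_mito`` / ``is_ribo`` (optional; QC adds them
        from name prefixes when absent).
    barcode_meta
        One row per barcode. Expected columns include ``sample`` and
        ``condition``; optional columns: ``age``, ``pmi``,
        ``cell_type``, ``umap_1``, ``umap_2``, ``doublet_score``,
        ``is_doublet``, ``pseudotime``, ``branch``.
    """

    counts: sp.spmatrix
    gene_meta: pd.DataFrame
    barcode_meta: pd.DataFrame
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape[0] != len(self.gene_meta):
            raise ValueError(
                f"counts has {self.counts.shape[0]} genes but gene_meta has "
                f"{len(self.gene_meta)} rows"
            )
        if self.counts.shape[1] != len(self.barcode_meta):
            raise ValueError(
                f"counts has {self.counts.shape[1]} barcodes but barcode_meta "
                f"has {len(self.barcode_meta)} rows"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if "condition" in self.barcode_meta.columns:
            bad = set(self.barcode_meta["condition"].unique()) - set(VALID_CONDITIONS)
            if bad:
                raise ValueError(
                    f"condition labels must be in {VALID_CONDITIONS}, got {sorted(bad)}"
                )
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.barcode_meta = self.barcode_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    @property
    def barcode_ids(self) -> np.ndarray:
        if "barcode" in self.barcode_meta.columns:
            return self.barcode_meta["barcode"].to_numpy()
        return np.array([f"bc{i:06d}" for i in range(self.n_barcodes)])

    def subset_barcodes(self, mask: np.ndarray) -> "CountAssay":
        """Return a new assay keeping barcodes where ``mask`` is True
        (or at the given integer positions), order preserved."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountAssay(
            counts=self.counts[:, idx],
            gene_meta=self.gene_meta.copy(),
            barcode_meta=self.barcode_meta.iloc[idx].reset_index(drop=True),
            uns=dict(self.uns),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountAssay":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountAssay(
            counts=self.counts[idx, :],
            gene_meta=self.gene_meta.iloc[idx].reset_index(drop=True),
            barcode_meta=self.barcode_meta.copy(),
            uns=dict(self.uns),
        )

    def embedding(self) -> np.ndarray:
        """(n_barcodes, 2) array of embedding coordinates."""
        cols = [c for c in ("umap_1", "umap_2") if c in self.barcode_meta.columns]
        if len(cols) != 2:
            raise ValueError("assay has no 2D embedding (umap_1/umap_2 missing)")
        return self.barcode_meta[cols].to_numpy(dtype=float)
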