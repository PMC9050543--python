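"""Barcode and gene filter cascade with per-stage attrition reporting.

The cascade keeps barcodes with more than ``min_umis`` UMIs and more
than ``min_genes`` detected genes, mitochondrial and ribosomal count
fractions strictly below their caps and (when a doublet score is
available) a doublet score strictly below ``max_doublet_score``; genes
must be detected in at least ``min_barcodes_per_gene`` barcodes, and
flagged mito/ribo genes are removed regardless of detection. Stage
order is barcode filter, then gene filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from nigra.assay import CountAssay

MITO_PREFIXES = ("MT-",)
RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class QCThresholds:
    """Filter thresholds. Strictness follows the stated rules:
    UMI/gene minima and the fraction/doublet caps are exclusive,
    ``min_barcodes_per_gene`` is inclusive (>=)."""

    min_umis: int = 1500
    min_genes: int = 1000
    max_mito_frac: float = 0.10
    max_ribo_frac: float = 0.10
    min_barcodes_per_gene: int = 3
    max_doublet_score: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "min_umis", "min_genes", "max_mito_frac",
            "max_ribo_frac", "min_barcodes_per_gene", "max_doublet_score",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def flag_genes(
    gene_meta: pd.DataFrame,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
    ribo_prefixes: tuple[str, ...] = RIBO_PREFIXES,
) -> pd.DataFrame:
    """Ensure is_mito / is_ribo flags exist, deriving them from gene-id
    prefixes when absent."""
    meta = gene_meta.copy()
    if "is_mito" not in meta.columns:
        meta["is_mito"] = meta["gene_id"].str.upper().str.startswith(mito_prefixes)
    if "is_ribo" not in meta.columns:
        meta["is_ribo"] = meta["gene_id"].str.upper().str.startswith(ribo_prefixes)
    return meta


def compute_barcode_metrics(assay: CountAssay) -> pd.DataFrame:
    """Per-barcode totals: UMIs, detected genes, mito/ribo fractions.

    Fractions use the raw (pre-filter) per-barcode UMI total as the
    denominator. All-zero barcodes get zero fractions and
    ``zero_umi_flag=True``.
    """
    meta = flag_genes(assay.gene_meta)
    counts = assay.counts.tocsc()
    umi_total = np.asarray(counts.sum(axis=0)).ravel()
    genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[meta["is_mito"].to_numpy(), :].sum(axis=0)).ravel()
    ribo = np.asarray(counts[meta["is_ribo"].to_numpy(), :].sum(axis=0)).ravel()
    zero = umi_total == 0
    if zero.any():
        import warnings

        warnings.warn(
            f"{int(zero.sum())} barcode(s) with zero UMIs; fractions set to 0",
            stacklevel=2,
        )
    denom = np.where(zero, 1, umi_total)
    return pd.DataFrame(
        {
            "umi_total": umi_total.astype(int),
            "genes_detected": genes_detected.astype(int),
            "mito_frac": np.where(zero, 0.0, mito / denom),
            "ribo_frac": np.where(zero, 0.0, ribo / denom),
            "zero_umi_flag": zero,
        }
    )


def filter_barcodes(
    assay: CountAssay, thr: QCThresholds | None = None
) -> tuple[CountAssay, dict]:
    """Apply the barcode criteria; return (filtered assay, report).

    The report lists the number of barcodes failing each criterion
    (overlaps allowed: a barcode can fail several) plus removed and
    retained totals. Barcode order is preserved. The doublet criterion
    is skipped, with an explicit notice, when no ``doublet_score``
    column is present.
    """
    thr = thr or QCThresholds()
    metrics = compute_barcode_metrics(assay)
    fails = {
        "low_umis": metrics["umi_total"].to_numpy() <= thr.min_umis,
        "low_genes": metrics["genes_detected"].to_numpy() <= thr.min_genes,
        "high_mito": metrics["mito_frac"].to_numpy() >= thr.max_mito_frac,
        "high_ribo": metrics["ribo_frac"].to_numpy() >= thr.max_ribo_frac,
    }
    notices = []
    if "doublet_score" in assay.barcode_meta.columns:
        fails["doublet"] = (
            assay.barcode_meta["doublet_score"].to_numpy() >= thr.max_doublet_score
        )
    else:
        notices.append("doublet_score absent; doublet criterion skipped")
    keep = ~np.logical_or.reduce(list(fails.values()))
    report = {
        "n_input": int(assay.n_barcodes),
        "removed_per_criterion": {k: int(v.sum()) for k, v in fails.items()},
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "notices": notices,
    }
    return assay.subset_barcodes(keep), report


def filter_genes(
    assay: CountAssay, thr: QCThresholds | None = None
) -> tuple[CountAssay, dict]:
    """Drop genes detected in fewer than ``min_barcodes_per_gene``
    barcodes (inclusive threshold), then drop all mito/ribo-flagged
    genes regardless of detection."""
    thr = thr or QCThresholds()
    meta = flag_genes(assay.gene_meta)
    detected_in = np.asarray((assay.counts > 0).sum(axis=1)).ravel()
    low_detection = detected_in < thr.min_barcodes_per_gene
    flagged = (meta["is_mito"] | meta["is_ribo"]).to_numpy()
    keep = ~(low_detection | flagged)
    report = {
        "n_input": int(assay.n_genes),
        "removed_per_criterion": {
            "low_detection": int(low_detection.sum()),
            "mito_or_ribo": int(flagged.sum()),
        },
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    out = assay.subset_genes(keep)
    out.gene_meta = flag_genes(out.gene_meta)
    return out, report


def run_qc(
    assay: CountAssay, thr: QCThresholds | None = None
) -> tuple[CountAssay, dict]:
    """Full cascade (barcode filter then gene filter) with a combined
    attrition report."""
    thr = thr or QCThresholds()
    filtered, barcode_report = filter_barcodes(assay, thr)
    filtered, gene_report = filter_genes(filtered, thr)
    return filtered, {"barcodes": barcode_report, "genes": gene_report}


def score_doublets_simple(
    assay: CountAssay,
    k: int = 20,
    n_sim: int | None = None,
    seed: int = 0,
    n_components: int = 20,
) -> np.ndarray:
    """Self-contained doublet score in [0, 1].

    Simulates ``n_sim`` doublets as sums of random barcode pairs,
    embeds observed + simulated profiles by truncated SVD of
    log1p-CP10K expression, and scores each observed barcode by the
    fraction of simulated doublets among its ``k`` nearest neighbors.
    Stand-in for an external doublet caller; deterministic given seed.
    """
    from sklearn.decomposition import TruncatedSVD
    from sklearn.neighbors import NearestNeighbors

    n = assay.n_barcodes
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of barcodes ({n})")
    if n < 2 * k:
        raise ValueError("need at least 2k barcodes")
    if n_sim is None:
        n_sim = n
    if n_sim == 0:
        return np.zeros(n)

    rng = np.random.default_rng(seed)
    counts = assay.counts.tocsc()
    pairs = rng.integers(0, n, size=(n_sim, 2))
    sim = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]
    combined = sp.hstack([counts, sim]).tocsc().astype(float)

    totals = np.asarray(combined.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    norm = combined.multiply(1e4 / totals).tocsc()
    norm.data = np.log1p(norm.data)

    n_comp = min(n_components, norm.shape[0] - 1)
    svd = TruncatedSVD(n_components=n_comp, random_state=seed)
    emb = svd.fit_transform(norm.T)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neighbor_is_sim = idx[:, 1:] >= n  # drop self
    return neighbor_is_sim.mean(axis=1)
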