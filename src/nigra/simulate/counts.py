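"""Synthetic multi-sample UMI count matrices with planted structure.

Cells are drawn per sample from condition-specific cell-type
proportions; each cell's counts are a Dirichlet-multinomial draw around
its type's expression profile, which yields gene-level overdispersion
relative to Poisson. A case-exclusive rare cluster is carved out of a
parent type, doublets are sums of two type profiles, and every cell
carries truth labels plus 2D Gaussian-mixture embedding coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from nigra.assay import CountAssay
from nigra.simulate.configs import SimCountsConfig

RARE_TYPE = "rare"


def simulate_filter_cascade_assay(
    n_barcodes: int,
    n_fail_umi: int = 0,
    n_fail_mito: int = 0,
    n_fail_doublet: int = 0,
    n_fail_mito_and_doublet: int = 0,
    umi_pass: int = 2000,
    umi_fail: int = 1000,
    seed: int = 0,
) -> CountAssay:
    """Minimal assay with a planted number of QC-failing barcodes.

    Builds a 4-gene matrix (one mito, one ribo, two filler genes) where
    the requested barcode counts fail, respectively, the UMI criterion,
    the mito-fraction criterion, the doublet criterion, or both of the
    latter; all remaining barcodes pass every default criterion except
    the detected-genes one (use ``min_genes=1`` with this fixture).
    Barcode order is shuffled deterministically by ``seed`` so failures
    are not positional.
    """
    n_fail = n_fail_umi + n_fail_mito + n_fail_doublet + n_fail_mito_and_doublet
    if n_fail > n_barcodes:
        raise ValueError("more failing barcodes than barcodes")
    rng = np.random.default_rng(seed)
    umi = np.full(n_barcodes, umi_pass, dtype=np.int64)
    mito_frac = np.full(n_barcodes, 0.05)
    doublet = np.full(n_barcodes, 0.05)
    edges = np.cumsum([n_fail_umi, n_fail_mito, n_fail_doublet, n_fail_mito_and_doublet])
    umi[: edges[0]] = umi_fail
    mito_frac[edges[0]: edges[1]] = 0.20
    doublet[edges[1]: edges[2]] = 0.20
    mito_frac[edges[2]: edges[3]] = 0.20
    doublet[edges[2]: edges[3]] = 0.20
    order = rng.permutation(n_barcodes)
    umi, mito_frac, doublet = umi[order], mito_frac[order], doublet[order]

    mito = np.round(umi * mito_frac).astype(np.int64)
    ribo = np.round(umi * 0.02).astype(np.int64)
    rest = umi - mito - ribo
    dense = np.vstack([mito, ribo, rest - rest // 2, rest // 2])
    gene_meta = pd.DataFrame(
        {
            "gene_id": ["MT-G0", "RPS0", "G00001", "G00002"],
            "is_mito": [True, False, False, False],
            "is_ribo": [False, True, False, False],
        }
    )
    barcode_meta = pd.DataFrame(
        {
            "barcode": [f"bc{i:06d}" for i in range(n_barcodes)],
            "sample": "pooled",
            "condition": "control",
            "doublet_score": doublet,
        }
    )
    truth = {
        "n_fail_total": int(n_fail),
        "n_fail_umi": n_fail_umi,
        "n_fail_mito": n_fail_mito + n_fail_mito_and_doublet,
        "n_fail_doublet": n_fail_doublet + n_fail_mito_and_doublet,
    }
    return CountAssay(
        counts=sp.csr_matrix(dense),
        gene_meta=gene_meta,
        barcode_meta=barcode_meta,
        uns={"truth": truth},
    )


def _gene_table(cfg: SimCountsConfig) -> pd.DataFrame:
    names = []
    is_mito = []
    is_ribo = []
    for i in range(cfg.n_genes):
        if i < cfg.n_mito_genes:
            names.append(f"MT-G{i}")
            is_mito.append(True)
            is_ribo.append(False)
        elif i < cfg.n_mito_genes + cfg.n_ribo_genes:
            j = i - cfg.n_mito_genes
            names.append(f"RPS{j}" if j % 2 == 0 else f"RPL{j}")
            is_mito.append(False)
            is_ribo.append(True)
        else:
            names.append(f"G{i:05d}")
            is_mito.append(False)
            is_ribo.append(False)
    return pd.DataFrame({"gene_id": names, "is_mito": is_mito, "is_ribo": is_ribo})


def _type_profiles(cfg: SimCountsConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str], dict]:
    """Expression weight vectors per type (incl. rare), rows on the simplex."""
    n_types = cfg.n_celltypes + 1  # last row = rare type
    base = rng.gamma(2.0, 1.0, size=cfg.n_genes) + 0.1
    # keep housekeeping (mito/ribo) weights modest so QC fractions are sane
    n_flagged = cfg.n_mito_genes + cfg.n_ribo_genes
    if n_flagged:
        base[:n_flagged] = 0.5 * base.mean()
    profiles = np.tile(base, (n_types, 1))
    free = np.arange(n_flagged, cfg.n_genes)
    marker_map: dict[str, list[int]] = {}
    for t in range(n_types):
        lo = t * cfg.marker_genes_per_type
        hi = lo + cfg.marker_genes_per_type
        if hi <= len(free):
            markers = free[lo:hi]
        else:  # more types than disjoint blocks: fall back to random markers
            markers = rng.choice(free, size=cfg.marker_genes_per_type, replace=False)
        profiles[t, markers] *= 8.0
        marker_map[_type_name(t, cfg)] = [int(m) for m in markers]
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles, [_type_name(t, cfg) for t in range(n_types)], marker_map


def _type_name(t: int, cfg: SimCountsConfig) -> str:
    return RARE_TYPE if t == cfg.n_celltypes else f"type_{t:02d}"


def _embedding_centers(cfg: SimCountsConfig) -> np.ndarray:
    n_types = cfg.n_celltypes + 1
    angles = 2 * np.pi * np.arange(n_types) / n_types
    radius = np.full(n_types, 10.0)
    radius[-1] = 15.0  # rare cluster sits outside the main ring
    return np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])


def simulate_counts(cfg: SimCountsConfig) -> CountAssay:
    """Generate a sparse gene x barcode assay with truth labels.

    Returns an assay whose ``barcode_meta`` carries sample, condition,
    age, PMI, true cell type, ``is_doublet`` and embedding coordinates,
    and whose ``uns['truth']`` records the planted configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_meta = _gene_table(cfg)
    profiles, type_names, marker_map = _type_profiles(cfg, rng)
    centers = _embedding_centers(cfg)
    lo, hi = cfg.libsize_range

    cols: list[sp.csc_matrix] = []
    rows_meta: list[dict] = []
    sample_ages = rng.normal(78.0, 5.0, size=cfg.n_samples)
    sample_pmi = rng.gamma(4.0, 5.0, size=cfg.n_samples)

    for s in range(cfg.n_samples):
        cond = cfg.conditions[s]
        props = np.asarray(cfg.base_proportions[cond], dtype=float)
        full = np.append(props, 0.0)
        if cond == "case" and cfg.rare_cluster_fraction > 0:
            full[cfg.rare_parent_type] -= cfg.rare_cluster_fraction
            full[-1] = cfg.rare_cluster_fraction
        batch = np.exp(rng.normal(0.0, cfg.batch_sd, size=cfg.n_genes))
        sample_profiles = profiles * batch
        sample_profiles /= sample_profiles.sum(axis=1, keepdims=True)

        n_cells = cfg.cells_per_sample
        types = rng.choice(len(full), size=n_cells, p=full)
        n_doublets = rng.binomial(n_cells, cfg.doublet_rate)
        doublet_idx = set(rng.choice(n_cells, size=n_doublets, replace=False).tolist())

        data = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
        for i in range(n_cells):
            t = types[i]
            is_doublet = i in doublet_idx
            if is_doublet:
                t2 = rng.choice(len(full), p=full)
                p = 0.5 * (sample_profiles[t] + sample_profiles[t2])
                xy = 0.5 * (centers[t] + centers[t2]) + rng.normal(0, 0.6, 2)
            else:
                p = sample_profiles[t]
                xy = centers[t] + rng.normal(0, 0.6, 2)
            libsize = int(rng.integers(lo, hi + 1))
            alpha = cfg.overdispersion * p
            q = rng.gamma(np.maximum(alpha, 1e-12))
            q_sum = q.sum()
            q = q / q_sum if q_sum > 0 else p
            data[:, i] = rng.multinomial(libsize, q)
            rows_meta.append(
                {
                    "barcode": f"s{s:02d}_bc{i:05d}",
                    "sample": f"sample_{s:02d}",
                    "condition": cond,
                    "age": float(sample_ages[s]),
                    "pmi": float(sample_pmi[s]),
                    "cell_type": type_names[t],
                    "is_doublet": bool(is_doublet),
                    "umap_1": float(xy[0]),
                    "umap_2": float(xy[1]),
                }
            )
        cols.append(sp.csc_matrix(data))

    counts = sp.hstack(cols).tocsr()
    barcode_meta = pd.DataFrame(rows_meta)
    truth = {
        "type_names": type_names,
        "rare_type": RARE_TYPE if cfg.rare_cluster_fraction > 0 else None,
        "rare_parent_type": _type_name(cfg.rare_parent_type, cfg),
        "embedding_centers": {t: centers[i].tolist() for i, t in enumerate(type_names)},
        "marker_genes": marker_map,
        "doublet_rate": cfg.doublet_rate,
        "seed": cfg.seed,
    }
    return CountAssay(counts=counts, gene_meta=gene_meta, barcode_meta=barcode_meta, uns={"truth": truth})
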