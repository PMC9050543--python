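import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nigra.assay import CountAssay
from nigra.simulate import SimCountsConfig, simulate_counts


@pytest.fixture(scope="session")
def small_assay() -> CountAssay:
    """Six-sample, four-type assay with a planted rare case cluster."""
    cfg = SimCountsConfig(
        n_samples=6,
        conditions=("case", "case", "case", "control", "control", "control"),
        n_celltypes=4,
        cells_per_sample=150,
        n_genes=120,
        marker_genes_per_type=8,
        rare_cluster_fraction=0.06,
        seed=42,
    )
    return simulate_counts(cfg)


@pytest.fixture()
def toy_assay() -> CountAssay:
    """Tiny dense assay for hand-checkable metrics."""
    counts = sp.csr_matrix(
        np.array(
            [
                [5, 0, 3],   # mito
                [15, 2, 0],
                [0, 0, 0],
                [1, 1, 1],   # ribo
            ]
        )
    )
    gene_meta = pd.DataFrame(
        {
            "gene_id": ["MT-A", "GENE1", "GENE2", "RPS9"],
            "is_mito": [True, False, False, False],
            "is_ribo": [False, False, False, True],
        }
    )
    barcode_meta = pd.DataFrame(
        {
            "barcode": ["b1", "b2", "b3"],
            "sample": ["s1", "s1", "s1"],
            "condition": ["case", "case", "case"],
        }
    )
    return CountAssay(counts, gene_meta, barcode_meta)
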