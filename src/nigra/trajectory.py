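"""Principal-graph pseudotime and trajectory-associated statistics.

The principal graph is a k-means + Euclidean-MST surrogate: centroids
in embedding space joined by a minimum spanning tree, with each cell
projected onto its nearest tree edge. Supervised rooting places the
root at the node maximizing the minimum geodesic distance to the nodes
nearest a designated activated cell subset; pseudotime is the geodesic
distance from the root to each cell's projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from nigra.assay import CountAssay
from nigra.composition import bh_adjust


@dataclass
class TrajectoryGraph:
    """Weighted tree over embedding space with cell->edge projections."""

    nodes: np.ndarray  # (n_nodes, 2)
    edges: list[tuple[int, int, float]]  # (u, v, length)
    cell_edge: np.ndarray  # per-cell index into edges
    cell_offset: np.ndarray  # arc length from edge endpoint u to projection
    root: int | None = None
    pseudotime: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        rows, cols, data = [], [], []
        for u, v, w in self.edges:
            rows += [u, v]
            cols += [v, u]
            data += [w, w]
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def node_distances(self) -> np.ndarray:
        return shortest_path(self.adjacency(), method="D", directed=False)

    def nearest_node_per_cell(self) -> np.ndarray:
        """For each cell, the closer endpoint of its projection edge."""
        out = np.empty(len(self.cell_edge), dtype=int)
        for i, (e, s) in enumerate(zip(self.cell_edge, self.cell_offset)):
            u, v, w = self.edges[e]
            out[i] = u if s <= w / 2 else v
        return out


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(distance to segment, arc offset from a), with clamping."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t * float(np.linalg.norm(ab))


def learn_principal_graph(
    embedding: np.ndarray, n_centroids: int, seed: int = 0
) -> TrajectoryGraph:
    """k-means centroids joined by a Euclidean MST, cells projected to
    the nearest edge point. Duplicate centroids are jittered with a
    warning."""
    from sklearn.cluster import KMeans

    embedding = np.asarray(embedding, dtype=float)
    if n_centroids < 2:
        raise ValueError("n_centroids must be >= 2")
    if len(embedding) < n_centroids:
        raise ValueError("fewer cells than centroids")
    km = KMeans(n_clusters=n_centroids, n_init=10, random_state=seed)
    km.fit(embedding)
    centers = km.cluster_centers_.copy()
    # jitter exact duplicates so the MST is well defined
    rng = np.random.default_rng(seed)
    for i in range(len(centers)):
        for j in range(i):
            if np.allclose(centers[i], centers[j]):
                import warnings

                warnings.warn("duplicate centroids jittered", stacklevel=2)
                centers[i] += rng.normal(0, 1e-6, centers.shape[1])

    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    from scipy.sparse.csgraph import minimum_spanning_tree

    mst = minimum_spanning_tree(dist).tocoo()
    edges = sorted(
        (min(int(u), int(v)), max(int(u), int(v)), float(w))
        for u, v, w in zip(mst.row, mst.col, mst.data)
    )

    cell_edge = np.empty(len(embedding), dtype=int)
    cell_offset = np.empty(len(embedding))
    for i, p in enumerate(embedding):
        best = (np.inf, 0, 0.0)
        for e, (u, v, _w) in enumerate(edges):
            d, s = _project_to_segment(p, centers[u], centers[v])
            if d < best[0]:
                best = (d, e, s)
        cell_edge[i] = best[1]
        cell_offset[i] = best[2]
    return TrajectoryGraph(
        nodes=centers, edges=edges, cell_edge=cell_edge, cell_offset=cell_offset,
        meta={"seed": seed},
    )


def root_supervised(
    g: TrajectoryGraph, activated_cells: np.ndarray
) -> TrajectoryGraph:
    """Root at the node maximizing the minimum geodesic distance to the
    nodes nearest the activated cells (tie -> lowest node id), then fill
    pseudotime as geodesic distance from the root to each projection."""
    activated_cells = np.asarray(activated_cells)
    if activated_cells.dtype == bool:
        activated_cells = np.flatnonzero(activated_cells)
    if len(activated_cells) == 0:
        raise ValueError("activated_cells must be non-empty")
    dmat = g.node_distances()
    if not np.isfinite(dmat).all():
        raise ValueError("principal graph is disconnected")
    anchor_nodes = np.unique(g.nearest_node_per_cell()[activated_cells])
    min_dist = dmat[:, anchor_nodes].min(axis=1)
    root = int(np.flatnonzero(min_dist == min_dist.max())[0])

    d_root = dmat[root]
    pt = np.empty(len(g.cell_edge))
    for i, (e, s) in enumerate(zip(g.cell_edge, g.cell_offset)):
        u, v, w = g.edges[e]
        pt[i] = min(d_root[u] + s, d_root[v] + (w - s))
    return TrajectoryGraph(
        nodes=g.nodes, edges=g.edges, cell_edge=g.cell_edge,
        cell_offset=g.cell_offset, root=root, pseudotime=pt, meta=dict(g.meta),
    )


def pseudotime_density_contrast(
    g: TrajectoryGraph, conditions: np.ndarray, grid_size: int = 200
) -> pd.DataFrame:
    """Gaussian kernel densities of pseudotime per condition on a shared
    grid, plus their difference (case - control)."""
    if g.pseudotime is None:
        raise ValueError("graph is not rooted; run root_supervised first")
    conditions = np.asarray(conditions)
    pt_case = g.pseudotime[conditions == "case"]
    pt_control = g.pseudotime[conditions == "control"]
    if len(pt_case) < 10 or len(pt_control) < 10:
        raise ValueError("need >= 10 cells per condition")
    if g.pseudotime.std() == 0:
        raise ValueError("pseudotime has zero variance")
    grid = np.linspace(g.pseudotime.min(), g.pseudotime.max(), grid_size)
    dens = {}
    for name, vals in (("case", pt_case), ("control", pt_control)):
        if vals.std() == 0:
            raise ValueError(f"zero-variance pseudotime in {name} cells")
        d = stats.gaussian_kde(vals)(grid)
        dens[name] = d / np.trapezoid(d, grid)  # renormalize truncated mass
    return pd.DataFrame(
        {
            "pseudotime": grid,
            "density_case": dens["case"],
            "density_control": dens["control"],
            "difference": dens["case"] - dens["control"],
        }
    )


# ---------------------------------------------------------------------------
# Moran's I


def knn_weight_matrix(
    embedding: np.ndarray, k: int = 15
) -> sp.csr_matrix:
    """Row-standardized, average-symmetrized k-nearest-neighbor weights."""
    from sklearn.neighbors import NearestNeighbors

    n = len(embedding)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
    graph = nn.kneighbors_graph(embedding)  # binary, includes self
    graph.setdiag(0)
    graph.eliminate_zeros()
    w = (graph + graph.T) / 2.0
    return w.tocsr()


def _row_standardize(weights: sp.spmatrix) -> sp.csr_matrix:
    w = sp.csr_matrix(weights, dtype=float)
    rs = np.asarray(w.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    return (sp.diags(1.0 / rs) @ w).tocsr()


def _weight_moments(w: sp.csr_matrix) -> tuple[float, float, float]:
    """Cliff-Ord S0, S1, S2 for a (row-standardized) weight matrix."""
    s0 = float(w.sum())
    sym = w + w.T
    s1 = 0.5 * float(sym.multiply(sym).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    return s0, s1, s2


def _morans_i_one(
    w: sp.csr_matrix, moments: tuple[float, float, float], x: np.ndarray
) -> dict:
    n = len(x)
    e_i = -1.0 / (n - 1)
    if x.std() == 0:
        return {"I": np.nan, "expected": e_i, "z": np.nan, "p": np.nan,
                "undefined": True}
    s0, s1, s2 = moments
    z = x - x.mean()
    I = n / s0 * float(z @ (w @ z)) / float(z @ z)
    # variance under the randomization assumption (Cliff-Ord)
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num_var = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den_var = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num_var / den_var - e_i**2
    zscore = (I - e_i) / np.sqrt(var_i)
    return {"I": float(I), "expected": e_i, "z": float(zscore),
            "p": float(stats.norm.sf(zscore)), "undefined": False}


def morans_i(weights: sp.spmatrix, expr: np.ndarray) -> dict:
    """Moran's I with z/p under the randomization assumption.

    I = (n / sum W) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2
    after row-standardizing the weights. Constant expression is flagged
    undefined rather than reported as 0. One-sided (positive
    autocorrelation) p-value.
    """
    x = np.asarray(expr, dtype=float)
    w = _row_standardize(weights)
    return _morans_i_one(w, _weight_moments(w), x)


def morans_i_genes(
    assay: CountAssay,
    weights: sp.spmatrix | None = None,
    k: int = 15,
) -> pd.DataFrame:
    """Moran's I per gene on a cell kNN graph, BH-adjusted across genes."""
    if weights is None:
        weights = knn_weight_matrix(assay.embedding(), k=k)
    w = _row_standardize(weights)
    moments = _weight_moments(w)
    expr = np.asarray(assay.counts.todense(), dtype=float)
    rows = []
    for gi in range(assay.n_genes):
        res = _morans_i_one(w, moments, expr[gi])
        res["gene_id"] = assay.gene_ids[gi]
        rows.append(res)
    out = pd.DataFrame(rows)
    defined = ~out["undefined"]
    q = np.full(len(out), np.nan)
    if defined.any():
        q[defined.to_numpy()] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["q"] = q
    return out[["gene_id", "I", "expected", "z", "p", "q", "undefined"]]


# ---------------------------------------------------------------------------
# quasi-Poisson differential expression


def default_size_factors(counts: sp.spmatrix) -> np.ndarray:
    """Per-cell total counts divided by their geometric mean."""
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts; filter first")
    return totals / np.exp(np.log(totals).mean())


def quasi_poisson_de(
    assay: CountAssay,
    condition: np.ndarray | None = None,
    size_factors: np.ndarray | None = None,
    dispersion_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene quasi-Poisson GLM: log E[y] = b0 + b1*case + log(sf).

    The dispersion is the Pearson chi-square scale (floored at
    ``dispersion_floor`` so standard errors never shrink below
    Poisson); Wald test on the condition coefficient, BH q-values.
    All-zero genes are excluded and listed in ``attrs['excluded']``.
    """
    import statsmodels.api as sm

    if condition is None:
        condition = assay.barcode_meta["condition"].to_numpy()
    condition = np.asarray(condition)
    if set(pd.unique(condition)) != {"case", "control"}:
        raise ValueError("need both 'case' and 'control' cells")
    if size_factors is None:
        size_factors = default_size_factors(assay.counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    offset = np.log(size_factors)
    X = sm.add_constant((condition == "case").astype(float))

    dense = np.asarray(assay.counts.todense())
    rows, excluded = [], []
    for gi in range(assay.n_genes):
        y = dense[gi]
        if y.sum() == 0:
            excluded.append(assay.gene_ids[gi])
            continue
        model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        try:
            res = model.fit()
        except Exception:
            excluded.append(assay.gene_ids[gi])
            continue
        df_resid = max(res.df_resid, 1)
        scale = max(float(res.pearson_chi2) / df_resid, dispersion_floor)
        se = float(res.bse[1]) * np.sqrt(scale)  # Poisson fit has scale 1
        coef = float(res.params[1])
        zval = coef / se
        rows.append(
            {
                "gene_id": assay.gene_ids[gi],
                "coef": coef,
                "se": se,
                "z": zval,
                "p": 2 * stats.norm.sf(abs(zval)),
                "dispersion": scale,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    out.attrs["excluded"] = excluded
    return out


def intersect_de_trajectory(
    de: pd.DataFrame,
    mi: pd.DataFrame,
    direction: str = "up",
    max_q: float = 0.05,
) -> list[str]:
    """Genes significant in both analyses with the requested DE sign.

    ``direction='up'`` keeps positive condition coefficients,
    ``'down'`` negative. Output is sorted for determinism.
    """
    universe = set(de["gene_id"]) & set(mi["gene_id"])
    if not universe:
        raise ValueError("empty shared gene universe")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    de_hits = set(
        de[(de["q"] < max_q) & (sign * de["coef"] > 0)]["gene_id"]
    )
    mi_hits = set(mi[(mi["q"] < max_q) & ~mi["undefined"]]["gene_id"])
    return sorted(de_hits & mi_hits & universe)
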