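import heapq

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nigra.assay import CountAssay
from nigra.simulate import SimTrajectoryConfig, simulate_trajectory
from nigra.trajectory import (
    TrajectoryGraph,
    default_size_factors,
    intersect_de_trajectory,
    knn_weight_matrix,
    learn_principal_graph,
    morans_i,
    pseudotime_density_contrast,
    quasi_poisson_de,
    root_supervised,
)


def dijkstra_oracle(edges, n_nodes, source):
    """Independent shortest-path oracle (binary heap, hand-rolled)."""
    adj = {i: [] for i in range(n_nodes)}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    dist = {i: np.inf for i in range(n_nodes)}
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            if d + w < dist[v]:
                dist[v] = d + w
                heapq.heappush(heap, (d + w, v))
    return dist


def _path_graph(cells_per_edge=5):
    """Hand-built path A(0)-B(1)-C(2), cells projected along it."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    edges = [(0, 1, 1.0), (1, 2, 1.0)]
    cell_edge, cell_offset = [], []
    for e in range(2):
        for s in np.linspace(0.1, 0.9, cells_per_edge):
            cell_edge.append(e)
            cell_offset.append(s)
    return TrajectoryGraph(
        nodes=nodes, edges=edges,
        cell_edge=np.array(cell_edge), cell_offset=np.array(cell_offset),
    )


# --------------------------------------------------------------- learn graph


def test_collinear_cells_give_path_graph():
    x = np.linspace(0, 10, 200)
    cells = np.column_stack([x, np.zeros_like(x)])
    g = learn_principal_graph(cells, n_centroids=3, seed=0)
    G = nx.Graph()
    G.add_weighted_edges_from(g.edges)
    degrees = sorted(d for _, d in G.degree())
    assert degrees == [1, 1, 2]
    # projections preserve order along the line
    order_in = np.argsort(x)
    pt_like = np.array(
        [g.nodes[g.edges[e][0], 0] + s for e, s in zip(g.cell_edge, g.cell_offset)]
    )
    assert (np.diff(pt_like[order_in]) >= -1e-9).all()


def test_y_shape_topology_recovered():
    cfg = SimTrajectoryConfig(n_cells=900, seed=3)
    assay = simulate_trajectory(cfg)
    g = learn_principal_graph(assay.embedding(), n_centroids=12, seed=0)
    G = nx.Graph()
    G.add_weighted_edges_from(g.edges)
    leaves = [n for n, d in G.degree() if d == 1]
    branchers = [n for n, d in G.degree() if d >= 3]
    assert len(leaves) == 3       # matches the 3 tips of the planted Y
    assert len(branchers) == 1    # single junction after degree-2 contraction


def test_learn_graph_deterministic():
    rng = np.random.default_rng(0)
    cells = rng.standard_normal((300, 2))
    a = learn_principal_graph(cells, 8, seed=5)
    b = learn_principal_graph(cells, 8, seed=5)
    np.testing.assert_array_equal(a.nodes, b.nodes)
    assert a.edges == b.edges
    np.testing.assert_array_equal(a.cell_edge, b.cell_edge)


def test_learn_graph_input_validation():
    cells = np.random.default_rng(0).standard_normal((10, 2))
    with pytest.raises(ValueError, match="n_centroids"):
        learn_principal_graph(cells, 1)
    with pytest.raises(ValueError, match="fewer cells"):
        learn_principal_graph(cells, 50)


# ------------------------------------------------------------------- rooting


def test_path_rooting_endpoint_logic():
    g = _path_graph()
    # activated cells = those on the far edge near C
    activated = np.flatnonzero(
        (g.cell_edge == 1) & (g.cell_offset > 0.5)
    )
    rooted = root_supervised(g, activated)
    assert rooted.root == 0
    # pseudotime monotone along the path A->C
    arc = np.array(
        [rooted.edges[e][0] + s for e, s in zip(g.cell_edge, g.cell_offset)]
    )
    order = np.argsort(arc)
    assert (np.diff(rooted.pseudotime[order]) >= -1e-12).all()


def test_two_branch_rooting_matches_bruteforce_maximin():
    # Y tree: 0-1 (junction), 1-2 and 1-3 tips; extra stem 4-0
    nodes = np.array([[0, 0], [2, 0], [3, 1], [3, -1], [-2, 0.0]])
    edges = [(0, 1, 2.0), (1, 2, 1.5), (1, 3, 1.5), (0, 4, 2.0)]
    cell_edge = np.array([1, 2])      # one cell near each tip
    cell_offset = np.array([1.4, 1.4])
    g = TrajectoryGraph(nodes=nodes, edges=edges, cell_edge=cell_edge,
                        cell_offset=cell_offset)
    rooted = root_supervised(g, np.array([0, 1]))
    # oracle: exhaustive maximin over all nodes with hand Dijkstra
    anchors = [2, 3]  # nodes nearest the two cells
    best, best_d = None, -1
    for v in range(5):
        dist = dijkstra_oracle(edges, 5, v)
        d = min(dist[a] for a in anchors)
        if d > best_d:
            best, best_d = v, d
    assert rooted.root == best


def test_pseudotime_equals_dijkstra_oracle_exactly():
    rng = np.random.default_rng(7)
    cells = rng.standard_normal((400, 2)) * 3
    g = learn_principal_graph(cells, n_centroids=20, seed=1)
    rooted = root_supervised(g, np.arange(10))
    dist = dijkstra_oracle(rooted.edges, rooted.n_nodes, rooted.root)
    for i in range(len(cells)):
        u, v, w = rooted.edges[rooted.cell_edge[i]]
        s = rooted.cell_offset[i]
        expected = min(dist[u] + s, dist[v] + (w - s))
        assert rooted.pseudotime[i] == pytest.approx(expected, abs=1e-12)


def test_rooting_all_cells_activated_finite():
    g = _path_graph()
    rooted = root_supervised(g, np.arange(len(g.cell_edge)))
    assert np.isfinite(rooted.pseudotime).all()
    assert rooted.root is not None


def test_rooting_empty_activated_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        root_supervised(_path_graph(), np.array([], dtype=int))


def test_rooting_disconnected_rejected():
    g = _path_graph()
    g.edges = [(0, 1, 1.0)]  # drop edge to node 2
    g.cell_edge = np.zeros_like(g.cell_edge)
    with pytest.raises(ValueError, match="disconnected"):
        root_supervised(g, np.array([0]))


# ---------------------------------------------------------- density contrast


def _rooted_sim(shift, seed=0, n=800):
    cfg = SimTrajectoryConfig(n_cells=n, condition_shift=shift, seed=seed)
    assay = simulate_trajectory(cfg)
    g = learn_principal_graph(assay.embedding(), n_centroids=10, seed=0)
    pt = assay.barcode_meta["pseudotime"]
    act = (pt >= pt.quantile(0.9)).to_numpy()  # >=: the shift piles cells at the tip
    return assay, root_supervised(g, act)


def test_contrast_recovers_planted_shift():
    assay, rooted = _rooted_sim(shift=2.0, seed=1)
    curve = pseudotime_density_contrast(rooted, assay.barcode_meta["condition"].to_numpy())
    grid = curve["pseudotime"].to_numpy()
    mean_case = np.trapezoid(curve["density_case"] * grid, grid)
    mean_ctrl = np.trapezoid(curve["density_control"] * grid, grid)
    assert mean_case > mean_ctrl
    upper = grid > np.quantile(grid, 0.8)
    assert curve.loc[upper, "difference"].mean() > 0


def test_contrast_densities_integrate_to_one():
    assay, rooted = _rooted_sim(shift=0.0, seed=2)
    curve = pseudotime_density_contrast(rooted, assay.barcode_meta["condition"].to_numpy())
    grid = curve["pseudotime"].to_numpy()
    assert np.trapezoid(curve["density_case"], grid) == pytest.approx(1.0, abs=1e-9)
    assert np.trapezoid(curve["density_control"], grid) == pytest.approx(1.0, abs=1e-9)


def test_contrast_null_difference_small():
    assay, rooted = _rooted_sim(shift=0.0, seed=3, n=1500)
    conditions = assay.barcode_meta["condition"].to_numpy()
    curve = pseudotime_density_contrast(rooted, conditions)
    # bootstrap SE of the difference under label exchange
    rng = np.random.default_rng(0)
    diffs = []
    for _ in range(60):
        perm = rng.permutation(conditions)
        c = pseudotime_density_contrast(rooted, perm)
        diffs.append(np.abs(c["difference"]).max())
    assert np.abs(curve["difference"]).max() < 3 * np.std(diffs) + np.mean(diffs)


def test_contrast_needs_both_conditions():
    g = _path_graph()
    g.root, g.pseudotime = 0, np.linspace(0, 1, len(g.cell_edge))
    with pytest.raises(ValueError, match="10 cells"):
        pseudotime_density_contrast(g, np.array(["case"] * len(g.cell_edge)))


# ------------------------------------------------------------------- Moran's


def _chain_weights(n):
    w = sp.lil_matrix((n, n))
    for i in range(n - 1):
        w[i, i + 1] = 1
        w[i + 1, i] = 1
    return w.tocsr()


def test_moran_smooth_chain_high():
    n = 100
    res = morans_i(_chain_weights(n), np.arange(n, dtype=float))
    assert res["I"] > 0.9


def test_moran_permutation_mean_near_null():
    rng = np.random.default_rng(0)
    n = 60
    w = _chain_weights(n)
    x = rng.standard_normal(n)
    vals = []
    for _ in range(1000):
        vals.append(morans_i(w, rng.permutation(x))["I"])
    mean_i = np.mean(vals)
    se = np.std(vals) / np.sqrt(len(vals))
    assert abs(mean_i - (-1 / (n - 1))) < 3 * se


def test_moran_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    n = 50
    pts = rng.standard_normal((n, 2))
    w = knn_weight_matrix(pts, k=5)
    x = rng.standard_normal(n)
    res = morans_i(w, x)
    # oracle: row-standardize densely, O(n^2) double loop
    wd = (w.toarray())
    wd = wd / wd.sum(axis=1, keepdims=True)
    xbar = x.mean()
    num = sum(
        wd[i, j] * (x[i] - xbar) * (x[j] - xbar)
        for i in range(n) for j in range(n)
    )
    den = sum((x[i] - xbar) ** 2 for i in range(n))
    expected = n / wd.sum() * num / den
    assert res["I"] == pytest.approx(expected, abs=1e-12)


def test_moran_affine_invariance():
    rng = np.random.default_rng(2)
    w = _chain_weights(40)
    x = rng.standard_normal(40)
    a = morans_i(w, x)
    b = morans_i(w, 3.5 * x - 7.0)
    assert a["I"] == pytest.approx(b["I"], abs=1e-12)
    assert a["z"] == pytest.approx(b["z"], abs=1e-9)


def test_moran_constant_flagged_undefined():
    res = morans_i(_chain_weights(10), np.ones(10))
    assert res["undefined"]
    assert np.isnan(res["I"])


# ------------------------------------------------------------------------ DE


def _de_assay(n_per_group=100, n_genes=20, logfc=0.0, seed=0):
    """Gene 0 carries the planted logFC; the rest are null so size
    factors are not confounded with the condition."""
    rng = np.random.default_rng(seed)
    cond = np.array(["control"] * n_per_group + ["case"] * n_per_group)
    mu = np.full((n_genes, 2 * n_per_group), 5.0)
    mu[0, n_per_group:] *= np.exp(logfc)
    shape = 2.0  # NB dispersion 0.5
    counts = rng.poisson(rng.gamma(shape, mu / shape))
    gm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)]})
    bm = pd.DataFrame({"sample": "s", "condition": cond})
    return CountAssay(sp.csr_matrix(counts), gm, bm)


def test_de_offset_invariance():
    assay = _de_assay(seed=3)
    sf = default_size_factors(assay.counts)
    res1 = quasi_poisson_de(assay, size_factors=sf)
    doubled = assay.counts.toarray()
    cond = assay.barcode_meta["condition"].to_numpy()
    doubled[:, cond == "case"] *= 2
    assay2 = CountAssay(sp.csr_matrix(doubled), assay.gene_meta, assay.barcode_meta)
    sf2 = sf.copy()
    sf2[cond == "case"] *= 2
    res2 = quasi_poisson_de(assay2, size_factors=sf2)
    np.testing.assert_allclose(res1["coef"], res2["coef"], atol=1e-8)


def test_de_recovers_logfc_roughly():
    est = [
        quasi_poisson_de(_de_assay(logfc=1.0, seed=s))["coef"].iloc[0]
        for s in range(15)
    ]
    assert abs(np.mean(est) - 1.0) < 0.15


def test_de_all_zero_gene_excluded():
    assay = _de_assay(seed=4)
    dense = assay.counts.toarray()
    dense[2] = 0
    assay2 = CountAssay(sp.csr_matrix(dense), assay.gene_meta, assay.barcode_meta)
    res = quasi_poisson_de(assay2)
    assert "g2" in res.attrs["excluded"]
    assert "g2" not in set(res["gene_id"])


def test_de_dispersion_floor():
    res = quasi_poisson_de(_de_assay(seed=5))
    assert (res["dispersion"] >= 1.0).all()


def test_de_requires_both_conditions():
    assay = _de_assay()
    with pytest.raises(ValueError, match="case"):
        quasi_poisson_de(assay, condition=np.array(["case"] * assay.n_barcodes))


def test_size_factors_positive_geometric_mean():
    assay = _de_assay(seed=6)
    sf = default_size_factors(assay.counts)
    assert (sf > 0).all()
    assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)


# --------------------------------------------------------------- intersection


def _fake_de(genes, qs, coefs):
    return pd.DataFrame({"gene_id": genes, "q": qs, "coef": coefs})


def _fake_mi(genes, qs):
    return pd.DataFrame({"gene_id": genes, "q": qs, "undefined": False})


def test_intersect_disjoint_empty():
    de = _fake_de(["a", "b"], [0.01, 0.9], [1.0, 1.0])
    mi = _fake_mi(["a", "b"], [0.9, 0.01])
    assert intersect_de_trajectory(de, mi) == []


def test_intersect_direction_flip_complementary():
    de = _fake_de(["a", "b", "c"], [0.01, 0.01, 0.01], [1.0, -1.0, 2.0])
    mi = _fake_mi(["a", "b", "c"], [0.01, 0.01, 0.01])
    up = intersect_de_trajectory(de, mi, "up")
    down = intersect_de_trajectory(de, mi, "down")
    assert up == ["a", "c"]
    assert down == ["b"]
    assert set(up) | set(down) == {"a", "b", "c"}


def test_intersect_empty_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        intersect_de_trajectory(_fake_de([], [], []), _fake_mi(["a"], [0.5]))


def test_intersect_sorted_deterministic():
    de = _fake_de(["z", "a", "m"], [0.01] * 3, [1.0] * 3)
    mi = _fake_mi(["z", "a", "m"], [0.01] * 3)
    assert intersect_de_trajectory(de, mi) == ["a", "m", "z"]
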