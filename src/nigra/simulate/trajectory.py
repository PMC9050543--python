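"""Synthetic branched cell continua with known pseudotime.

The latent topology is a tree laid out deterministically in the plane.
Each cell is placed on a root-to-tip path at a known arc-length
position (its true pseudotime); case cells headed to an activated tip
are displaced along the path by ``condition_shift``. Counts are
negative binomial with per-gene mean profiles tied to pseudotime.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
import scipy.sparse as sp

from nigra.assay import CountAssay
from nigra.simulate.configs import SimTrajectoryConfig


def _layout_tree(cfg: SimTrajectoryConfig) -> dict[int, np.ndarray]:
    """Deterministic planar layout: children fan out over angle ranges."""
    g = nx.Graph(list(cfg.branch_topology))
    pos: dict[int, np.ndarray] = {cfg.root_node: np.zeros(2)}

    def place(node: int, parent: int | None, lo: float, hi: float) -> None:
        children = sorted(n for n in g.neighbors(node) if n != parent)
        if not children:
            return
        span = (hi - lo) / len(children)
        for i, child in enumerate(children):
            ang = lo + span * (i + 0.5)
            pos[child] = pos[node] + cfg.edge_length * np.array(
                [np.cos(ang), np.sin(ang)]
            )
            place(child, node, ang - span / 2.5, ang + span / 2.5)

    place(cfg.root_node, None, -np.pi / 2, np.pi / 2)
    return pos


def _root_paths(cfg: SimTrajectoryConfig) -> dict[int, list[int]]:
    g = nx.Graph(list(cfg.branch_topology))
    tips = sorted(n for n in g.nodes if g.degree[n] == 1 and n != cfg.root_node)
    if not tips:  # degenerate 2-node tree rooted at a leaf
        tips = [n for n in g.nodes if n != cfg.root_node]
    return {t: nx.shortest_path(g, cfg.root_node, t) for t in tips}


def _gene_means(cfg: SimTrajectoryConfig, pt_norm: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(n_genes, n_cells) mean matrix and boolean trajectory-gene mask."""
    n, g = len(pt_norm), cfg.n_genes
    is_traj = np.zeros(g, dtype=bool)
    is_traj[: cfg.n_trajectory_genes] = True
    log_mu = np.full((g, n), np.log(cfg.base_mean))
    signs = np.where(np.arange(g) % 2 == 0, 1.0, -1.0)
    for j in range(cfg.n_trajectory_genes):
        if cfg.effect_profile == "monotone":
            log_mu[j] += signs[j] * cfg.effect_size * (pt_norm - 0.5)
        elif cfg.effect_profile == "switch":
            log_mu[j] += signs[j] * cfg.effect_size * (
                1.0 / (1.0 + np.exp(-10.0 * (pt_norm - 0.5))) - 0.5
            )
        # flat: no pseudotime dependence even for "trajectory" genes
    log_mu += rng.normal(0.0, 0.2, size=(g, 1))  # per-gene baseline wiggle
    return np.exp(log_mu), is_traj


def simulate_trajectory(cfg: SimTrajectoryConfig) -> CountAssay:
    """Generate cells along a branched trajectory with NB counts.

    ``barcode_meta`` carries true pseudotime, branch (the tip whose
    root path the cell sits on), condition and embedding coordinates;
    ``uns['truth']`` records topology, node positions and the
    trajectory-gene mask.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = _layout_tree(cfg)
    paths = _root_paths(cfg)
    tips = sorted(paths)
    path_len = {t: cfg.edge_length * (len(paths[t]) - 1) for t in tips}

    n = cfg.n_cells
    conditions = np.where(
        rng.random(n) < cfg.case_fraction, "case", "control"
    )
    cell_tip = rng.choice(tips, size=n)
    pt = np.empty(n)
    xy = np.empty((n, 2))
    for i in range(n):
        tip = cell_tip[i]
        L = path_len[tip]
        u = rng.uniform(0.0, L)
        if (
            conditions[i] == "case"
            and cfg.condition_shift != 0.0
            and tip in cfg.activated_tips
        ):
            u = float(np.clip(u + cfg.condition_shift, 0.0, L))
        pt[i] = u
        # locate the edge of the root->tip path containing arc length u
        k = min(int(u // cfg.edge_length), len(paths[tip]) - 2)
        a, b = paths[tip][k], paths[tip][k + 1]
        frac = (u - k * cfg.edge_length) / cfg.edge_length
        xy[i] = pos[a] + frac * (pos[b] - pos[a]) + rng.normal(0, cfg.noise_sd, 2)

    max_len = max(path_len.values())
    means, is_traj = _gene_means(cfg, pt / max_len, rng)
    # NB via gamma-Poisson: shape 1/dispersion, Var = mu + dispersion*mu^2
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, means / shape)
    counts = sp.csr_matrix(rng.poisson(lam))

    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(cfg.n_genes)],
            "is_mito": False,
            "is_ribo": False,
            "is_trajectory_gene": is_traj,
        }
    )
    barcode_meta = pd.DataFrame(
        {
            "barcode": [f"bc{i:06d}" for i in range(n)],
            "sample": "sim",
            "condition": conditions,
            "cell_type": [cfg.branch_tip_labels.get(t, f"tip_{t}") for t in cell_tip],
            "branch": cell_tip,
            "pseudotime": pt,
            "umap_1": xy[:, 0],
            "umap_2": xy[:, 1],
        }
    )
    truth = {
        "topology": [list(e) for e in cfg.branch_topology],
        "root_node": cfg.root_node,
        "node_positions": {int(k): v.tolist() for k, v in pos.items()},
        "activated_tips": list(cfg.activated_tips),
        "trajectory_genes": np.flatnonzero(is_traj).tolist(),
        "condition_shift": cfg.condition_shift,
        "seed": cfg.seed,
    }
    return CountAssay(counts=counts, gene_meta=gene_meta, barcode_meta=barcode_meta, uns={"truth": truth})
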