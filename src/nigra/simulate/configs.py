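"""Configuration dataclasses for the synthetic generators.

Every generator is a pure function of (config, seed): the seed lives in
the config and identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SIMPLEX_TOL = 1e-12


@dataclass
class SimCountsConfig:
    """Plan for a multi-sample case/control count matrix.

    ``base_proportions`` maps each condition to a simplex vector of
    length ``n_celltypes``. In case samples a fraction
    ``rare_cluster_fraction`` of the cells of ``rare_parent_type`` is
    relabelled as a case-exclusive rare type.
    """

    n_samples: int = 11
    conditions: tuple[str, ...] = (
        "case", "case", "case", "case", "case", "case",
        "control", "control", "control", "control", "control",
    )
    n_celltypes: int = 12
    cells_per_sample: int = 300
    base_proportions: dict[str, tuple[float, ...]] | None = None
    rare_cluster_fraction: float = 0.0
    rare_parent_type: int = 0
    n_genes: int = 500
    marker_genes_per_type: int = 10
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    batch_sd: float = 0.1
    libsize_range: tuple[int, int] = (1501, 4000)
    doublet_rate: float = 0.0
    overdispersion: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_proportions is None:
            p = np.full(self.n_celltypes, 1.0 / self.n_celltypes)
            self.base_proportions = {"control": tuple(p), "case": tuple(p)}
        if len(self.conditions) != self.n_samples:
            raise ValueError("conditions must have one label per sample")
        for cond, props in self.base_proportions.items():
            props = np.asarray(props, dtype=float)
            if len(props) != self.n_celltypes:
                raise ValueError(
                    f"base_proportions[{cond!r}] has {len(props)} entries, "
                    f"expected {self.n_celltypes}"
                )
            if abs(props.sum() - 1.0) > _SIMPLEX_TOL or (props < 0).any():
                bad = [
                    f"sample {i}" for i, c in enumerate(self.conditions) if c == cond
                ]
                raise ValueError(
                    f"base_proportions for condition {cond!r} is not a simplex "
                    f"(affects {', '.join(bad) or 'no samples'})"
                )
        if not 0.0 <= self.rare_cluster_fraction <= 1.0:
            raise ValueError("rare_cluster_fraction must be in [0, 1]")
        if self.rare_cluster_fraction > 0:
            parent = np.asarray(self.base_proportions["case"])[self.rare_parent_type]
            if self.rare_cluster_fraction >= parent:
                raise ValueError(
                    "rare_cluster_fraction must be smaller than the parent "
                    "type's case proportion"
                )
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must be in [0, 1)")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must be a pair of positive ints, lo <= hi")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")


@dataclass
class SimTrajectoryConfig:
    """Plan for a branched continuum of cells with trajectory genes.

    ``branch_topology`` is a tree given as an edge list over integer
    latent nodes; cells live on its edges. ``effect_profile`` assigns
    each trajectory gene a shape along pseudotime: ``monotone`` (log
    mean linear in pseudotime) or ``switch`` (sigmoid at the midpoint).
    """

    n_cells: int = 2000
    branch_topology: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (1, 3))
    root_node: int = 0
    branch_tip_labels: dict[int, str] = field(
        default_factory=lambda: {2: "activated_a", 3: "activated_b"}
    )
    activated_tips: tuple[int, ...] | None = None
    condition_shift: float = 0.0
    case_fraction: float = 0.5
    n_genes: int = 100
    n_trajectory_genes: int = 20
    effect_profile: str = "monotone"
    effect_size: float = 1.5
    base_mean: float = 2.0
    dispersion: float = 0.5
    edge_length: float = 3.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.branch_topology)
        if g.number_of_nodes() and not nx.is_tree(g):
            raise ValueError("branch_topology must be a tree (connected, acyclic)")
        if self.root_node not in g.nodes:
            raise ValueError(f"root node {self.root_node} not in branch_topology")
        if self.n_trajectory_genes > self.n_genes:
            raise ValueError("n_trajectory_genes must be <= n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.effect_profile not in ("monotone", "switch", "flat"):
            raise ValueError("effect_profile must be monotone, switch or flat")
        if self.activated_tips is None:
            self.activated_tips = tuple(sorted(self.branch_tip_labels))
        tips = {n for n in g.nodes if g.degree[n] == 1}
        for t in self.activated_tips:
            if t not in tips:
                raise ValueError(f"activated tip {t} is not a leaf of the topology")


@dataclass
class CellMorphology:
    """Parametric star-shaped cell: soma disc plus radiating processes."""

    branch_count: int = 4
    soma_radius: float = 6.0
    process_length: float = 15.0
    process_width: int = 3

    def __post_init__(self) -> None:
        if self.branch_count < 0:
            raise ValueError("branch_count must be >= 0")


@dataclass
class SimImageConfig:
    """Plan for a synthetic multi-channel fluorescence field.

    Bright channels (TH, GFAP, IBA1, PLP1) render objects above
    ``background_level``; NM is a dark-object channel (deposits darker
    than background). The region layout splits the canvas into
    quadrants labelled SN, NR, TT and CC.
    """

    width: int = 256
    height: int = 256
    channels: tuple[str, ...] = ("IBA1",)
    n_cells_per_channel: int = 10
    morphology: CellMorphology = field(default_factory=CellMorphology)
    background_level: float = 1000.0
    foreground_level: float = 8000.0
    noise_sd: float = 0.0
    region_layout: str = "quadrants"
    pixel_size: float = 0.5
    seed: int = 0

    VALID_CHANNELS = ("TH", "NM", "GFAP", "IBA1", "PLP1")

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel must be requested")
        for c in self.channels:
            if c not in self.VALID_CHANNELS:
                raise ValueError(f"unknown channel {c!r}")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if isinstance(self.morphology, dict):
            self.morphology = CellMorphology(**self.morphology)


@dataclass
class SimGeneStatsConfig:
    """Plan for per-gene association statistics with planted set shifts."""

    n_genes: int = 10000
    n_sets: int = 10
    set_sizes: tuple[int, ...] | int = 200
    enriched_sets: tuple[int, ...] = ()
    delta: float = 0.0
    covariate_effects: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.set_sizes, int):
            self.set_sizes = tuple([self.set_sizes] * self.n_sets)
        if len(self.set_sizes) != self.n_sets:
            raise ValueError("set_sizes must have one entry per set")
        for s in self.set_sizes:
            if s > self.n_genes:
                raise ValueError("set sizes must not exceed n_genes")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        for s in self.enriched_sets:
            if not 0 <= s < self.n_sets:
                raise ValueError(f"enriched set index {s} out of range")
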