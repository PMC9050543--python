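"""Differential cell-type composition analyses.

2D kernel density contrast on the embedding, per-sample proportion
t-tests, beta regression of proportions on clinical covariates,
pseudobulk transcriptome similarity and one-vs-rest ROC marker scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster import hierarchy

from nigra.assay import CountAssay

_EPS_VAR = 1e-12


# ---------------------------------------------------------------------------
# embedding density


@dataclass
class DensityField:
    """Normalized 2D kernel density on a rectangular grid."""

    x_grid: np.ndarray  # bin centers, length = bins
    y_grid: np.ndarray
    density: np.ndarray  # (bins, bins), x along axis 0

    @property
    def cell_area(self) -> float:
        return float((self.x_grid[1] - self.x_grid[0]) * (self.y_grid[1] - self.y_grid[0]))


@dataclass
class DensityGrid:
    """Case/control densities on a shared grid plus their log2 ratio."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density_case: np.ndarray
    density_control: np.ndarray
    log2_ratio: np.ndarray  # masked (NaN) where both densities < floor
    floor: float


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth (Scott-type, as in classic 2D KDE)."""
    n = len(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sd = x.std(ddof=1)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 1.06 * spread * n ** (-1 / 5)


def embedding_density(
    points: np.ndarray,
    bins: int = 100,
    extent: tuple[float, float, float, float] | None = None,
    bandwidth: tuple[float, float] | None = None,
) -> DensityField:
    """Gaussian product-kernel density of 2D points on a bins x bins grid.

    The grid covers ``extent`` (xmin, xmax, ymin, ymax; defaults to the
    data range). The returned density is renormalized to integrate to 1
    over the grid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(points) < 10:
        raise ValueError("need at least 10 cells for a density estimate")
    for ax, name in ((0, "x"), (1, "y")):
        if points[:, ax].std() == 0 and bandwidth is None:
            raise ValueError(f"degenerate embedding: zero variance along {name}")
    if extent is None:
        extent = (
            points[:, 0].min(), points[:, 0].max(),
            points[:, 1].min(), points[:, 1].max(),
        )
    if bandwidth is None:
        bandwidth = (_nrd_bandwidth(points[:, 0]), _nrd_bandwidth(points[:, 1]))
    hx = max(bandwidth[0], 1e-9)
    hy = max(bandwidth[1], 1e-9)
    x_grid = np.linspace(extent[0], extent[1], bins)
    y_grid = np.linspace(extent[2], extent[3], bins)
    # mean over cells of the product kernel, evaluated on the grid
    kx = stats.norm.pdf((x_grid[:, None] - points[None, :, 0]) / hx) / hx
    ky = stats.norm.pdf((y_grid[:, None] - points[None, :, 1]) / hy) / hy
    density = kx @ ky.T / len(points)
    cell = (x_grid[1] - x_grid[0]) * (y_grid[1] - y_grid[0])
    density /= density.sum() * cell  # renormalize mass lost at the edges
    return DensityField(x_grid=x_grid, y_grid=y_grid, density=density)


def condition_densities(
    assay: CountAssay, bins: int = 100
) -> tuple[DensityField, DensityField]:
    """Case and control densities on a shared grid spanning the union range."""
    xy = assay.embedding()
    cond = assay.barcode_meta["condition"].to_numpy()
    extent = (
        xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max(),
    )
    case = embedding_density(xy[cond == "case"], bins=bins, extent=extent)
    control = embedding_density(xy[cond == "control"], bins=bins, extent=extent)
    return case, control


def differential_density(
    case_d: DensityField, control_d: DensityField, floor: float | None = None
) -> DensityGrid:
    """log2((case + floor) / (control + floor)); grid cells where both
    densities are below the floor are masked (NaN)."""
    if case_d.density.shape != control_d.density.shape or not np.allclose(
        case_d.x_grid, control_d.x_grid
    ) or not np.allclose(case_d.y_grid, control_d.y_grid):
        raise ValueError("case and control densities are on different grids")
    if floor is None:
        # default: one cell's worth of mass spread over the grid extent
        total_area = case_d.cell_area * case_d.density.size
        floor = 1.0 / total_area
    ratio = np.log2((case_d.density + floor) / (control_d.density + floor))
    masked = (case_d.density < floor) & (control_d.density < floor)
    ratio = np.where(masked, np.nan, ratio)
    return DensityGrid(
        x_grid=case_d.x_grid,
        y_grid=case_d.y_grid,
        density_case=case_d.density,
        density_control=control_d.density,
        log2_ratio=ratio,
        floor=float(floor),
    )


# ---------------------------------------------------------------------------
# proportions


def proportion_table(assay: CountAssay) -> pd.DataFrame:
    """Per (sample, cell_type) counts and within-sample proportions,
    carrying sample covariates."""
    meta = assay.barcode_meta
    covs = [c for c in ("condition", "age", "pmi") if c in meta.columns]
    counts = (
        meta.groupby(["sample", "cell_type"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    # include zero rows so every sample has every type
    full = (
        counts.set_index(["sample", "cell_type"])["count"]
        .unstack(fill_value=0)
        .stack()
        .rename("count")
        .reset_index()
    )
    totals = full.groupby("sample")["count"].transform("sum")
    full["proportion"] = full["count"] / totals
    sample_covs = meta.drop_duplicates("sample").set_index("sample")[covs]
    return full.merge(sample_covs, left_on="sample", right_index=True)


def proportion_test(
    tbl: pd.DataFrame, cell_type: str, equal_var: bool = True
) -> dict:
    """Two-sided two-sample t-test on per-sample proportions.

    Pooled-variance (classical Student) by default; Welch via
    ``equal_var=False``. Zero within-group variance is handled with a
    small variance guard rather than returning NaN.
    """
    sub = tbl[tbl["cell_type"] == cell_type]
    groups = {c: g["proportion"].to_numpy(dtype=float) for c, g in sub.groupby("condition")}
    for cond in ("case", "control"):
        if len(groups.get(cond, [])) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
    a, b = groups["case"], groups["control"]
    na, nb = len(a), len(b)
    if equal_var:
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        se = np.sqrt(max(sp2, _EPS_VAR) * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        va = max(a.var(ddof=1), _EPS_VAR)
        vb = max(b.var(ddof=1), _EPS_VAR)
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (a.mean() - b.mean()) / se
    p = 2 * stats.t.sf(abs(t), df)
    return {
        "t": float(t),
        "p": float(p),
        "df": float(df),
        "mean_case": float(a.mean()),
        "mean_control": float(b.mean()),
        "cell_type": cell_type,
    }


# ---------------------------------------------------------------------------
# beta regression


@dataclass
class BetaRegFit:
    """Beta-regression fit (logit mean link, constant precision)."""

    params: pd.Series  # mean-model coefficients on the logit scale
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    precision: float
    converged: bool
    cell_type: str


def _squeeze_proportions(y: np.ndarray) -> np.ndarray:
    """Pull boundary values into (0,1): (y*(n-1) + 0.5) / n.

    Applied only when boundary values are present — the transform
    otherwise distorts logit contrasts on interior data.
    """
    if (y > 0).all() and (y < 1).all():
        return y
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(
    tbl: pd.DataFrame,
    cell_type: str,
    covariates: tuple[str, ...] = ("condition", "age", "pmi"),
) -> BetaRegFit:
    """ML beta regression of a cell type's per-sample proportion on
    sample covariates; Wald tests per coefficient.

    Non-convergence is flagged on the result, never silently replaced.
    """
    from statsmodels.othermod.betareg import BetaModel

    sub = tbl[tbl["cell_type"] == cell_type].copy()
    y = _squeeze_proportions(sub["proportion"].to_numpy(dtype=float))
    X = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
    for cov in covariates:
        if cov == "condition":
            X["condition"] = (sub["condition"] == "case").astype(float)
        else:
            X[cov] = sub[cov].astype(float)
    if len(sub) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} samples to fit, got {len(sub)}"
        )
    model = BetaModel(y, X)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)
    mean_params = res.params[: X.shape[1]]
    precision = float(np.exp(res.params[X.shape[1]:]).item())
    ci = res.conf_int()
    ci_df = pd.DataFrame(
        np.asarray(ci)[: X.shape[1]], index=X.columns, columns=["lo", "hi"]
    )
    return BetaRegFit(
        params=pd.Series(np.asarray(mean_params), index=X.columns),
        bse=pd.Series(np.asarray(res.bse)[: X.shape[1]], index=X.columns),
        pvalues=pd.Series(np.asarray(res.pvalues)[: X.shape[1]], index=X.columns),
        conf_int=ci_df,
        precision=precision,
        converged=bool(res.mle_retvals.get("converged", True)),
        cell_type=cell_type,
    )


# ---------------------------------------------------------------------------
# pseudobulk similarity


def pseudobulk_similarity(
    assay: CountAssay, labels: np.ndarray | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation of per-type pseudobulk profiles and an
    average-linkage hierarchy on 1 - r.

    Pseudobulk = per-type summed counts, scaled to counts per million,
    log2(x + 1) transformed. Returns (correlation matrix, scipy linkage
    matrix). Types with zero total counts are excluded with a warning.
    """
    if labels is None:
        labels = assay.barcode_meta["cell_type"].to_numpy()
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    counts = assay.counts.tocsc()
    profiles = {}
    for t in types:
        total = np.asarray(counts[:, labels == t].sum(axis=1)).ravel()
        if total.sum() == 0:
            import warnings

            warnings.warn(f"cell type {t!r} has zero total counts; excluded", stacklevel=2)
            continue
        cpm = total / total.sum() * 1e6
        profiles[t] = np.log2(cpm + 1)
    mat = pd.DataFrame(profiles)
    corr = mat.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform

    linkage = hierarchy.average(squareform(dist, checks=False))
    return corr, linkage


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = render(node.left), render(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# ROC marker scoring


def _normalize_cp10k_log(counts: sp.spmatrix) -> sp.csr_matrix:
    totals = np.asarray(counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    norm = counts.multiply(1e4 / totals).tocsr()
    norm.data = np.log1p(norm.data)
    return norm


def roc_marker_scores(
    assay: CountAssay, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """One-vs-rest marker statistics per (gene, cell type).

    AUC of the gene's log1p-CP10K expression as a classifier of the
    type, logFC = ln(mean_in + 1) - ln(mean_out + 1) on normalized
    expression, detection percentages, Wilcoxon rank-sum p with BH
    correction across genes within each type.
    """
    if labels is None:
        labels = assay.barcode_meta["cell_type"].to_numpy()
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("marker scoring needs at least 2 labels")
    norm = _normalize_cp10k_log(assay.counts).toarray()
    genes = assay.gene_ids
    rows = []
    for t in types:
        in_mask = labels == t
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        x_in = norm[:, in_mask]
        x_out = norm[:, ~in_mask]
        mean_in = x_in.mean(axis=1)
        mean_out = x_out.mean(axis=1)
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        pvals = np.ones(len(genes))
        aucs = np.full(len(genes), 0.5)
        for g in range(len(genes)):
            a, b = x_in[g], x_out[g]
            if a.max() == a.min() == b.max() == b.min():
                continue
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            aucs[g] = u / (n_in * n_out)
            pvals[g] = p
        qvals = bh_adjust(pvals)
        for g in range(len(genes)):
            rows.append(
                {
                    "gene_id": genes[g],
                    "cell_type": t,
                    "auc": aucs[g],
                    "logFC": float(np.log(mean_in[g] + 1) - np.log(mean_out[g] + 1)),
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                    "p": pvals[g],
                    "q": qvals[g],
                }
            )
    return pd.DataFrame(rows)


def filter_markers(
    marker_table: pd.DataFrame,
    max_fdr: float = 0.05,
    min_pct: float = 0.5,
    min_logfc: float = 0.25,
) -> pd.DataFrame:
    """Apply the three marker thresholds (all strict inequalities):
    FDR-adjusted p < max_fdr, pct_in > min_pct, logFC > min_logfc."""
    return marker_table[
        (marker_table["q"] < max_fdr)
        & (marker_table["pct_in"] > min_pct)
        & (marker_table["logFC"] > min_logfc)
    ].reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
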