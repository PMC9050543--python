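"""Competitive gene-set association of marker genes with disease risk.

Gene-level association p-values are inputs; the module converts them to
z-scores and regresses z on set membership (plus optional covariates)
over the whole gene universe, testing one-sided for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def p_to_z(p: np.ndarray | float) -> np.ndarray | float:
    """z = Phi^-1(1 - p) for p in (0, 1]."""
    arr = np.asarray(p, dtype=float)
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def z_to_p(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`p_to_z`."""
    arr = np.asarray(z, dtype=float)
    p = stats.norm.sf(arr)
    return float(p) if np.isscalar(z) or arr.ndim == 0 else p


@dataclass
class SetAssociation:
    """Result of one competitive gene-set regression."""

    set_id: str
    beta: float
    se: float
    p: float  # one-sided, H1: beta > 0
    ci_lo: float
    ci_hi: float
    n_set: int
    n_universe: int
    gene_z: pd.DataFrame  # per-gene z within the set

    @property
    def effect_exp(self) -> float:
        """exp(beta) convenience column for forest-style display."""
        return float(np.exp(self.beta))


def competitive_set_test(
    tbl: pd.DataFrame,
    set_col: str,
    covariates: tuple[str, ...] = (),
    robust: bool = False,
) -> SetAssociation:
    """OLS of gene z-scores on set membership over the full universe.

    z_g = alpha + beta*1[g in set] + gamma'c_g + eps, one-sided Wald
    test of beta > 0. Covariate columns are used as given (log-transform
    upstream if desired). The set must be a non-empty strict subset of
    the universe.
    """
    member = tbl[set_col].to_numpy(dtype=float)
    n_set = int(member.sum())
    if n_set == 0:
        raise ValueError(f"set {set_col!r} is empty")
    if n_set == len(tbl):
        raise ValueError(f"set {set_col!r} equals the gene universe; no competitive contrast")
    import statsmodels.api as sm

    z = tbl["z"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(tbl)), member]
        + [tbl[c].to_numpy(dtype=float) for c in covariates]
    )
    res = sm.OLS(z, X).fit(cov_type="HC1" if robust else "nonrobust")
    beta = float(res.params[1])
    se = float(res.bse[1])
    df = res.df_resid
    p_one = float(stats.t.sf(beta / se, df))
    tcrit = stats.t.ppf(0.975, df)
    in_set = tbl[member.astype(bool)]
    gene_z = in_set[["gene_id", "z"]].sort_values("z", ascending=False).reset_index(drop=True)
    return SetAssociation(
        set_id=set_col,
        beta=beta,
        se=se,
        p=p_one,
        ci_lo=beta - tcrit * se,
        ci_hi=beta + tcrit * se,
        n_set=n_set,
        n_universe=len(tbl),
        gene_z=gene_z,
    )


def marker_sets_from_scores(
    marker_table: pd.DataFrame,
    max_fdr: float = 0.05,
    min_pct: float = 0.5,
    min_logfc: float = 0.25,
) -> pd.DataFrame:
    """Binary gene x cell-type membership from a marker score table.

    Applies the three thresholds exactly as stated (strict
    inequalities): FDR q < max_fdr, pct_in > min_pct, logFC > min_logfc.
    Requires columns gene_id, cell_type, q, pct_in, logFC.
    """
    required = {"gene_id", "cell_type", "q", "pct_in", "logFC"}
    missing = required - set(marker_table.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    passing = marker_table[
        (marker_table["q"] < max_fdr)
        & (marker_table["pct_in"] > min_pct)
        & (marker_table["logFC"] > min_logfc)
    ]
    genes = sorted(marker_table["gene_id"].unique())
    membership = pd.DataFrame(0, index=genes, columns=sorted(marker_table["cell_type"].unique()))
    for _, row in passing.iterrows():
        membership.loc[row["gene_id"], row["cell_type"]] = 1
    membership.index.name = "gene_id"
    return membership


def top_contributors(assoc: SetAssociation, k: int = 5) -> pd.DataFrame:
    """Top-k genes of the set ranked by z descending, ties broken
    lexicographically by gene id."""
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = assoc.gene_z.sort_values(
        ["z", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return ranked.head(k)
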