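"""Cross-validated verification of cell-type annotations.

Loess mean-variance normalization of log counts, per-class subsampling
to the median class size, repeated stratified 70/30 splits (or strict
k-fold), truncated-SVD reduction and a random-forest classifier,
aggregated into a confusion matrix with per-class precision/recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nigra.assay import CountAssay


@dataclass
class CVConfig:
    n_splits: int = 5
    train_frac: float = 0.7
    n_components: int = 30
    subsample_to: int | None = None  # default: median class size
    strict_kfold: bool = False
    loess_frac: float = 0.3
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


def loess_normalize(
    counts, loess_frac: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Scale genes by a loess fit of variance on mean of log1p counts.

    Each gene is centered at its mean and divided by the square root of
    its fitted variance. Returns (normalized genes x cells matrix,
    zero-variance flag per gene); zero-variance genes come out as
    all-zero rows.
    """
    import scipy.sparse as sp
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    logx = np.log1p(np.asarray(counts, dtype=float))
    means = logx.mean(axis=1)
    variances = logx.var(axis=1)
    zero_var = variances == 0
    fitted = np.full_like(variances, np.nan)
    ok = ~zero_var
    if ok.sum() >= 2:
        sm_fit = lowess(variances[ok], means[ok], frac=loess_frac, return_sorted=False)
        fitted[ok] = np.maximum(sm_fit, 1e-12)
    elif ok.any():
        fitted[ok] = variances[ok]
    out = np.zeros_like(logx)
    out[ok] = (logx[ok] - means[ok, None]) / np.sqrt(fitted[ok, None])
    return out, zero_var


def _subsample(labels: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Indices capping every class at ``cap`` cells, order-stable."""
    keep = []
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


def stratified_cv(
    assay: CountAssay,
    cfg: CVConfig | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Run the stratified CV and aggregate a confusion matrix.

    Returns a dict with ``confusion`` (rows = true labels, columns =
    predicted, aggregated over all test folds), ``metrics`` (per-class
    precision/recall), ``accuracy``, and ``untestable`` classes (fewer
    members than splits after subsampling; reported, not dropped
    silently).
    """
    from sklearn.decomposition import TruncatedSVD
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

    cfg = cfg or CVConfig()
    if labels is None:
        labels = assay.barcode_meta["cell_type"].to_numpy()
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)

    norm, _ = loess_normalize(assay.counts, cfg.loess_frac)
    X_all = norm.T  # cells x genes

    counts_per_class = pd.Series(labels).value_counts()
    cap = cfg.subsample_to or int(np.median(counts_per_class))
    idx = _subsample(labels, cap, rng)
    X, y = X_all[idx], labels[idx]

    kept_counts = pd.Series(y).value_counts()
    untestable = sorted(kept_counts[kept_counts < cfg.n_splits].index)
    testable = ~np.isin(y, untestable)
    X, y = X[testable], y[testable]

    if cfg.strict_kfold:
        splitter = StratifiedKFold(
            n_splits=cfg.n_splits, shuffle=True, random_state=cfg.seed
        )
        splits = splitter.split(X, y)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=cfg.n_splits,
            train_size=cfg.train_frac,
            random_state=cfg.seed,
        )
        splits = splitter.split(X, y)

    classes = sorted(pd.unique(y))
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    fold_test_counts = []
    for train_idx, test_idx in splits:
        fold_test_counts.append(
            pd.Series(y[test_idx]).value_counts().reindex(classes, fill_value=0)
        )
        n_comp = min(cfg.n_components, X.shape[1] - 1, len(train_idx) - 1)
        svd = TruncatedSVD(n_components=n_comp, random_state=cfg.seed)
        Z_train = svd.fit_transform(X[train_idx])
        Z_test = svd.transform(X[test_idx])
        clf = RandomForestClassifier(
            n_estimators=cfg.n_estimators, random_state=cfg.seed
        )
        clf.fit(Z_train, y[train_idx])
        pred = clf.predict(Z_test)
        for t, p in zip(y[test_idx], pred):
            confusion.loc[t, p] += 1

    total = confusion.to_numpy().sum()
    diag = np.diag(confusion.to_numpy()).sum()
    metrics = pd.DataFrame(
        {
            "precision": [
                confusion.loc[c, c] / m if (m := confusion[c].sum()) else np.nan
                for c in classes
            ],
            "recall": [
                confusion.loc[c, c] / m if (m := confusion.loc[c].sum()) else np.nan
                for c in classes
            ],
            "n_test": [int(confusion.loc[c].sum()) for c in classes],
        },
        index=classes,
    )
    return {
        "confusion": confusion,
        "metrics": metrics,
        "accuracy": float(diag / total) if total else np.nan,
        "untestable": untestable,
        "subsample_cap": cap,
        "fold_test_counts": pd.DataFrame(fold_test_counts).reset_index(drop=True),
        "class_counts": pd.Series(y).value_counts().reindex(classes, fill_value=0),
    }
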