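"""Automated immunofluorescence morphometry.

Per-channel segmentation (bright objects, or dark objects for the
neuromelanin channel), area fractions, microglial skeleton branching,
per-individual summaries and unpaired group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats
from skimage import morphology as skmorph

REGION_LABELS = {1: "SN", 2: "NR", 3: "TT", 4: "CC"}

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class ChannelStack:
    """Registered 2D intensity channels plus optional region labels."""

    channels: dict[str, np.ndarray]
    region_mask: np.ndarray | None = None
    pixel_size: float = 1.0
    truth_masks: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for c, a in self.channels.items():
            if np.asarray(a).min() < 0:
                raise ValueError(f"channel {c} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SegmentationParams:
    """Smoothing / threshold / cleanup settings for one channel.

    ``threshold_mode``: ``"absolute"`` interprets ``threshold`` as an
    intensity; ``"quantile"`` as a quantile of the channel in [0, 1].
    """

    gaussian_sigma: float = 0.0
    threshold: float = 0.5
    threshold_mode: str = "absolute"
    min_object_px: int = 0
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValueError("threshold_mode must be 'absolute' or 'quantile'")


def _resolve_threshold(channel: np.ndarray, p: SegmentationParams) -> float:
    if p.threshold_mode == "quantile":
        return float(np.quantile(channel, p.threshold))
    return float(p.threshold)


def _clean_and_label(binary: np.ndarray, p: SegmentationParams) -> np.ndarray:
    if p.min_object_px > 0:
        # drop components with area strictly below min_object_px
        lab, _ = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        binary = (sizes >= p.min_object_px)[lab]
    if p.fill_holes:
        binary = ndi.binary_fill_holes(binary)
    labels, _ = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    return labels


def segment_bright(channel: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Label mask of above-threshold objects (8-connected).

    Pipeline: optional Gaussian smoothing, binarize at >= threshold,
    drop components smaller than ``min_object_px``, optional hole
    filling, connected-component labeling.
    """
    channel = np.asarray(channel, dtype=float)
    smoothed = ndi.gaussian_filter(channel, p.gaussian_sigma) if p.gaussian_sigma > 0 else channel
    thr = _resolve_threshold(smoothed, p)
    if thr > smoothed.max():
        import warnings

        warnings.warn("threshold above maximum intensity; empty mask", stacklevel=2)
        return np.zeros_like(channel, dtype=np.int32)
    return _clean_and_label(smoothed >= thr, p)


def segment_dark(channel: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Label mask of below-threshold (dark) objects, e.g. neuromelanin."""
    channel = np.asarray(channel, dtype=float)
    smoothed = ndi.gaussian_filter(channel, p.gaussian_sigma) if p.gaussian_sigma > 0 else channel
    thr = _resolve_threshold(smoothed, p)
    if thr < smoothed.min():
        import warnings

        warnings.warn("threshold below minimum intensity; empty mask", stacklevel=2)
        return np.zeros_like(channel, dtype=np.int32)
    return _clean_and_label(smoothed <= thr, p)


def area_fraction(
    channel: np.ndarray,
    p: SegmentationParams,
    region_mask: np.ndarray | None = None,
    dark: bool = False,
) -> pd.DataFrame:
    """Positive-pixel fraction per region (plus a whole-image row).

    Regions with zero pixels get NaN and ``flag='empty_region'``.
    """
    channel = np.asarray(channel, dtype=float)
    smoothed = ndi.gaussian_filter(channel, p.gaussian_sigma) if p.gaussian_sigma > 0 else channel
    thr = _resolve_threshold(smoothed, p)
    positive = smoothed <= thr if dark else smoothed >= thr
    rows = [
        {
            "region": "all",
            "fraction": float(positive.mean()),
            "n_px": positive.size,
            "flag": "",
        }
    ]
    if region_mask is not None:
        if region_mask.shape != channel.shape:
            raise ValueError("region mask shape does not match channel")
        for rid, rname in REGION_LABELS.items():
            sel = region_mask == rid
            n = int(sel.sum())
            rows.append(
                {
                    "region": rname,
                    "fraction": float(positive[sel].mean()) if n else float("nan"),
                    "n_px": n,
                    "flag": "" if n else "empty_region",
                }
            )
    return pd.DataFrame(rows)


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbors at each skeleton pixel."""
    skel = skeleton.astype(np.uint8)
    counts = ndi.convolve(skel, _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return counts * skel


def prune_spurs(skeleton: np.ndarray, min_spur: int) -> np.ndarray:
    """Iteratively strip endpoint pixels ``min_spur`` times.

    Removes thinning artifacts shorter than ``min_spur`` px; genuine
    branches lose at most ``min_spur`` px of length but keep their
    branch point.
    """
    skel = skeleton.astype(bool).copy()
    for _ in range(min_spur):
        counts = neighbor_counts(skel)
        endpoints = (counts == 1) & skel
        if not endpoints.any():
            break
        skel[endpoints] = False
    return skel


def skeleton_branching(
    mask: np.ndarray, min_spur: int = 3
) -> pd.DataFrame:
    """Per-object skeleton statistics for a label (or binary) mask.

    For each object: thinning to a 1-px skeleton, optional spur
    pruning, then per object:

    - ``branch_px``: skeleton pixels with >= 3 skeleton neighbors
      (8-connectivity) — the raw junction-pixel count;
    - ``branch_points``: 8-connected clusters of those junction pixels
      (a thick junction registers once, e.g. a plus sign has exactly 1);
    - ``endpoints``: skeleton pixels with exactly 1 neighbor — for
      tree-shaped cells this equals the number of processes;
    - ``branching_index``: branch_points, plus the per-100-skeleton-px
      rate as an alternate.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    else:
        labels = mask.astype(np.int32)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    eight = np.ones((3, 3), dtype=int)
    rows = []
    for oid in ids:
        obj = labels == oid
        skel = skmorph.skeletonize(obj)
        skel = prune_spurs(skel, min_spur)
        counts = neighbor_counts(skel)
        skeleton_px = int(skel.sum())
        junctions = (counts >= 3) & skel
        branch_px = int(junctions.sum())
        _, branch_points = ndi.label(junctions, structure=eight)
        endpoints = int(((counts == 1) & skel).sum())
        rows.append(
            {
                "object_id": int(oid),
                "area_px": int(obj.sum()),
                "skeleton_px": skeleton_px,
                "branch_px": branch_px,
                "branch_points": int(branch_points),
                "endpoints": endpoints,
                "branching_index": int(branch_points),
                "branch_points_per_100px": (
                    100.0 * branch_points / skeleton_px if skeleton_px else 0.0
                ),
            }
        )
    cols = [
        "object_id", "area_px", "skeleton_px", "branch_px", "branch_points",
        "endpoints", "branching_index", "branch_points_per_100px",
    ]
    return pd.DataFrame(rows, columns=cols)


def object_features(
    labels: np.ndarray,
    region_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Area and perimeter per labeled object, with region assignment."""
    from skimage.measure import regionprops

    rows = []
    for prop in regionprops(labels):
        r, c = (int(round(v)) for v in prop.centroid)
        region = "all"
        if region_mask is not None:
            region = REGION_LABELS.get(int(region_mask[r, c]), "background")
        rows.append(
            {
                "object_id": int(prop.label),
                "area_px": int(prop.area),
                "area_um2": float(prop.area) * pixel_size**2,
                "perimeter_px": float(prop.perimeter),
                "region": region,
            }
        )
    cols = ["object_id", "area_px", "area_um2", "perimeter_px", "region"]
    return pd.DataFrame(rows, columns=cols)


def per_individual_summary(
    records: pd.DataFrame,
    individual_map: pd.DataFrame,
    value_cols: tuple[str, ...] = ("area_px",),
) -> pd.DataFrame:
    """Mean of per-object metrics per individual (and per region).

    ``records`` needs an ``image`` column; ``individual_map`` maps
    image -> individual, condition. Individuals contributing zero
    objects are excluded (with a notice column in the map output).
    """
    merged = records.merge(individual_map, on="image", how="left")
    if merged["individual"].isna().any():
        missing = sorted(records.loc[merged["individual"].isna(), "image"].unique())
        raise ValueError(f"images without individual mapping: {missing}")
    group_cols = ["individual", "condition"]
    if "region" in merged.columns:
        group_cols.append("region")
    out = (
        merged.groupby(group_cols, as_index=False)[list(value_cols)]
        .mean()
        .rename(columns={c: f"mean_{c}" for c in value_cols})
    )
    return out


def group_compare(
    summaries: pd.DataFrame,
    metric: str,
    region: str | None = None,
    equal_var: bool = True,
) -> dict:
    """Two-sided unpaired t-test on per-individual values."""
    df = summaries
    if region is not None and "region" in df.columns:
        df = df[df["region"] == region]
    groups = {c: g[metric].to_numpy(dtype=float) for c, g in df.groupby("condition")}
    if len(groups) != 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("group_compare needs two groups with >= 2 individuals each")
    labels = sorted(groups)
    a, b = groups[labels[0]], groups[labels[1]]
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "groups": labels,
        "means": {labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        "n": {labels[0]: int(len(a)), labels[1]: int(len(b))},
        "metric": metric,
        "region": region or "all",
    }
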