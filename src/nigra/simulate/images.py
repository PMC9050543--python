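"""Synthetic fluorescence fields with exact per-object ground truth.

Star-shaped cells (soma disc + radiating straight processes) for IBA1 /
GFAP, plain discs for TH, dark deposits on a bright background for NM
and diffuse multi-blob patches for PLP1. The truth label mask is
rasterized from the same geometry as the intensity image, so truth
areas and branch counts are exact.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk

from nigra.morphometry import ChannelStack
from nigra.simulate.configs import SimImageConfig

_REGION_IDS = {"SN": 1, "NR": 2, "TT": 3, "CC": 4}


def _region_mask(cfg: SimImageConfig) -> np.ndarray:
    mask = np.zeros((cfg.height, cfg.width), dtype=np.int32)
    h2, w2 = cfg.height // 2, cfg.width // 2
    mask[:h2, :w2] = _REGION_IDS["SN"]
    mask[:h2, w2:] = _REGION_IDS["NR"]
    mask[h2:, :w2] = _REGION_IDS["TT"]
    mask[h2:, w2:] = _REGION_IDS["CC"]
    return mask


def _stamp_disc(canvas: np.ndarray, center: tuple[float, float], radius: float, value) -> None:
    rr, cc = disk(center, radius, shape=canvas.shape)
    canvas[rr, cc] = value


def _stamp_process(
    canvas: np.ndarray,
    start: tuple[float, float],
    angle: float,
    length: float,
    width: int,
    value,
) -> None:
    # stamp overlapping small discs along the ray for a smooth wide line
    r = max(width / 2.0, 0.8)
    n_steps = max(int(np.ceil(length / (r / 2.0))), 2)
    for s in np.linspace(0.0, length, n_steps):
        cy = start[0] + s * np.sin(angle)
        cx = start[1] + s * np.cos(angle)
        _stamp_disc(canvas, (cy, cx), r, value)


def _render_star(
    labels: np.ndarray,
    center: tuple[float, float],
    branch_count: int,
    soma_radius: float,
    process_length: float,
    process_width: int,
    object_id: int,
    rng: np.random.Generator,
) -> None:
    _stamp_disc(labels, center, soma_radius, object_id)
    if branch_count > 0:
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(branch_count):
            ang = phase + 2 * np.pi * k / branch_count
            start = (
                center[0] + soma_radius * 0.9 * np.sin(ang),
                center[1] + soma_radius * 0.9 * np.cos(ang),
            )
            _stamp_process(
                labels, start, ang, process_length, process_width, object_id
            )


def _place_centers(
    cfg: SimImageConfig, n: int, radius: float, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], int]:
    """Best-effort non-overlapping placement; returns (centers, n_overlaps)."""
    centers: list[tuple[float, float]] = []
    overlaps = 0
    margin = radius + 2
    for _ in range(n):
        placed = False
        for _try in range(200):
            cy = rng.uniform(margin, cfg.height - margin)
            cx = rng.uniform(margin, cfg.width - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * radius) ** 2 for y, x in centers):
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            centers.append(
                (
                    rng.uniform(margin, cfg.height - margin),
                    rng.uniform(margin, cfg.width - margin),
                )
            )
            overlaps += 1
    return centers, overlaps


def simulate_images(cfg: SimImageConfig) -> ChannelStack:
    """Render the requested channels plus pixel-aligned truth masks.

    ``truth['objects'][channel]`` lists per-object id, truth area (px)
    and planted branch_count; ``truth['overlaps']`` counts objects that
    could not be placed without potential overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.morphology
    shape = (cfg.height, cfg.width)
    region = _region_mask(cfg)
    channels: dict[str, np.ndarray] = {}
    truth_masks: dict[str, np.ndarray] = {}
    objects: dict[str, list[dict]] = {}
    total_overlaps = 0

    for ch in cfg.channels:
        labels = np.zeros(shape, dtype=np.int32)
        reach = m.soma_radius + (m.process_length if ch in ("IBA1", "GFAP") else 0)
        centers, overlaps = _place_centers(cfg, cfg.n_cells_per_channel, reach, rng)
        total_overlaps += overlaps
        obj_list = []
        for i, center in enumerate(centers, start=1):
            if ch in ("IBA1", "GFAP"):
                _render_star(
                    labels, center, m.branch_count, m.soma_radius,
                    m.process_length, m.process_width, i, rng,
                )
                bc = m.branch_count
            elif ch in ("TH", "NM"):
                _stamp_disc(labels, center, m.soma_radius, i)
                bc = 0
            else:  # PLP1: diffuse patch = union of jittered blobs
                for _ in range(4):
                    off = rng.normal(0, m.soma_radius, 2)
                    _stamp_disc(
                        labels, (center[0] + off[0], center[1] + off[1]),
                        m.soma_radius, i,
                    )
                bc = 0
            obj_list.append(
                {
                    "object_id": i,
                    "area_px": int((labels == i).sum()),
                    "branch_count": int(bc),
                    "center": [float(center[0]), float(center[1])],
                }
            )
        fg = labels > 0
        if ch == "NM":
            img = np.full(shape, cfg.foreground_level)  # bright field
            img[fg] = cfg.background_level  # dark deposits
        else:
            img = np.full(shape, cfg.background_level)
            img[fg] = cfg.foreground_level
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, shape)
        channels[ch] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        truth_masks[ch] = labels
        objects[ch] = obj_list

    truth = {
        "objects": objects,
        "overlaps": total_overlaps,
        "seed": cfg.seed,
        "morphology": {
            "branch_count": m.branch_count,
            "soma_radius": m.soma_radius,
            "process_length": m.process_length,
        },
    }
    return ChannelStack(
        channels=channels,
        region_mask=region,
        pixel_size=cfg.pixel_size,
        truth_masks=truth_masks,
        truth=truth,
    )
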