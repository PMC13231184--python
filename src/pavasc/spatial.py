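"""2-D total-hemoglobin maps and consecutive-week hemoglobin-reduction masks.

Each week's THb volume is flattened to an en-face map (MIP by default),
mean-normalized within the ROI, Gaussian-smoothed, and differenced against
the previous week; pixels whose normalized THb dropped by more than the
threshold form the reduction mask used to localize at-risk regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ReductionMap",
    "flatten_thb",
    "mean_normalize",
    "gaussian_smooth",
    "reduction_map",
    "weekly_reduction_masks",
    "localization_score",
]


@dataclass
class ReductionMap:
    """Delta of smoothed, mean-normalized THb between consecutive weeks."""

    week_pair: tuple[int, int]
    delta: np.ndarray
    mask: np.ndarray
    threshold: float


def flatten_thb(
    thb: np.ndarray,
    skin_mask: np.ndarray,
    roi_mask_2d: np.ndarray,
    projection: str = "mip",
) -> np.ndarray:
    """Flatten a THb volume to an en-face map, zero outside the ROI.

    ``projection`` is ``"mip"`` (maximum over the masked Z extent, default)
    or ``"sum"``.
    """
    if not skin_mask.any():
        raise ValueError("skin mask is empty; nothing to flatten")
    if projection == "mip":
        masked = np.where(skin_mask, thb, -np.inf)
        out = masked.max(axis=2)
        out = np.where(np.isfinite(out), out, 0.0)
    elif projection == "sum":
        out = np.where(skin_mask, thb, 0.0).sum(axis=2)
    else:
        raise ValueError(f"unknown projection {projection!r}")
    return np.where(roi_mask_2d, out, 0.0)


def mean_normalize(map2d: np.ndarray, roi_mask_2d: np.ndarray) -> np.ndarray:
    """Divide by the ROI mean; the output has ROI mean exactly 1."""
    if not roi_mask_2d.any():
        raise ValueError("ROI is empty")
    mean = float(map2d[roi_mask_2d].mean())
    if mean <= 0:
        raise ValueError(f"ROI mean must be positive for normalization, got {mean}")
    return map2d / mean


def gaussian_smooth(map2d: np.ndarray, sigma_mm: float, spacing_mm: float = 0.1) -> np.ndarray:
    """Gaussian smoothing with sigma in mm (reflective boundaries); 0 = identity."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return map2d.copy()
    return gaussian_filter(map2d, sigma_mm / spacing_mm, mode="reflect")


def reduction_map(
    map_w1: np.ndarray,
    map_w2: np.ndarray,
    threshold: float = 0.15,
    week_pair: tuple[int, int] = (0, 0),
    roi_mask_2d: np.ndarray | None = None,
) -> ReductionMap:
    """Delta = week2 - week1 of mean-normalized, smoothed maps; mask where
    the drop exceeds ``threshold``."""
    if map_w1.shape != map_w2.shape:
        raise ValueError(f"map shapes differ: {map_w1.shape} vs {map_w2.shape}")
    delta = map_w2 - map_w1
    mask = delta < -threshold
    if roi_mask_2d is not None:
        mask &= roi_mask_2d
    return ReductionMap(week_pair=week_pair, delta=delta, mask=mask, threshold=threshold)


def weekly_reduction_masks(
    maps_by_week: Mapping[int, np.ndarray],
    roi_mask_2d: np.ndarray,
    threshold: float = 0.15,
    sigma_mm: float = 0.3,
    spacing_mm: float = 0.1,
    skip_first_pair: bool = True,
) -> list[ReductionMap]:
    """Mean-normalize, smooth and difference consecutive weekly THb maps.

    The first week pair is excluded by default (early post-implantation skin
    movement makes it unreliable).
    """
    weeks = sorted(maps_by_week)
    prepared = {
        w: gaussian_smooth(
            mean_normalize(maps_by_week[w], roi_mask_2d), sigma_mm, spacing_mm
        )
        for w in weeks
    }
    pairs = list(zip(weeks, weeks[1:]))
    if skip_first_pair and pairs:
        pairs = pairs[1:]
    return [
        reduction_map(
            prepared[w1], prepared[w2], threshold, week_pair=(w1, w2), roi_mask_2d=roi_mask_2d
        )
        for w1, w2 in pairs
    ]


def localization_score(
    reduction_masks: Sequence[ReductionMap | np.ndarray],
    truth_region: np.ndarray,
) -> dict[str, float]:
    """Dice / precision / recall of the union of reduction masks against a
    ground-truth at-risk region (synthetic runs only)."""
    if truth_region is None or not np.asarray(truth_region).any():
        raise ValueError("no ground-truth region available")
    masks = [m.mask if isinstance(m, ReductionMap) else np.asarray(m) for m in reduction_masks]
    if not masks:
        raise ValueError("no reduction masks given")
    union = np.zeros_like(truth_region, dtype=bool)
    for m in masks:
        union |= m.astype(bool)
    truth = truth_region.astype(bool)
    inter = float((union & truth).sum())
    denom = float(union.sum() + truth.sum())
    dice = 2 * inter / denom if denom else 0.0
    precision = inter / union.sum() if union.any() else 0.0
    recall = inter / truth.sum()
    return {"dice": dice, "precision": float(precision), "recall": float(recall)}
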