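"""Water-skin interface detection, skin-shell extraction, ROIs and water
normalization.

The interface is found per lateral column along Z: the first run of
super-threshold US voxels marks the top of the tissue.  A 3x3 lateral median
filter on the interface depth suppresses speckle-induced spikes.  The skin
shell is the configured thickness of tissue immediately below the interface
(Z-directed erosion from the interface side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .core import Volume3D

__all__ = [
    "SkinSegmentation",
    "find_tissue_mask",
    "extract_skin_shell",
    "make_roi_mask",
    "normalize_to_water",
    "segment_session",
]

logger = logging.getLogger(__name__)


@dataclass
class SkinSegmentation:
    """Binary tissue/skin-shell/water masks plus the lateral ROI."""

    tissue_mask: np.ndarray
    skin_mask: np.ndarray
    water_mask: np.ndarray
    interface_depth: np.ndarray  # mm, NaN where no tissue was found
    roi_mask_2d: Optional[np.ndarray] = None
    n_excluded_columns: int = 0

    def __post_init__(self) -> None:
        if (self.skin_mask & ~self.tissue_mask).any():
            raise ValueError("skin_mask must be a subset of tissue_mask")
        if (self.skin_mask & self.water_mask).any():
            raise ValueError("skin_mask and water_mask must be disjoint")


def find_tissue_mask(
    us: Volume3D,
    method: str = "otsu",
    threshold: Optional[float] = None,
    min_run: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the US volume into tissue below and water above the interface.

    Parameters
    ----------
    us : Volume3D
        Ultrasound volume (linear-scale echo amplitude).
    method : {"otsu", "fixed"}
        Threshold selection.  ``"fixed"`` requires ``threshold``.
    min_run : int
        Minimum number of consecutive super-threshold voxels that counts as
        tissue (rejects isolated noise spikes above the skin).

    Returns
    -------
    (tissue_mask, water_mask, interface_depth)
        ``interface_depth`` is in mm (top edge of the first tissue voxel)
        and NaN for lateral columns where no tissue was found; such columns
        are counted and logged.
    """
    values = us.values
    if values.max() <= 0:
        raise ValueError("no tissue detected: US volume is empty")
    if method == "otsu":
        if values.min() == values.max():
            raise ValueError("no tissue detected: US volume is constant")
        thr = float(threshold_otsu(values))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold method requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    above = values > thr
    nz = values.shape[2]
    # first index of a run of >= min_run consecutive super-threshold voxels
    run = np.zeros(above.shape[:2], dtype=int)
    first = np.full(above.shape[:2], -1, dtype=int)
    for k in range(nz):
        run = np.where(above[:, :, k], run + 1, 0)
        hit = (run == min_run) & (first < 0)
        first[hit] = k - min_run + 1
    valid = first >= 0
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise ValueError("no tissue detected: no lateral column crosses the threshold")
    if n_excluded:
        logger.warning("%d lateral columns contain no tissue; excluded", n_excluded)

    dz = us.spacing[2]
    # median-filter the interface (3x3 lateral) to suppress speckle spikes
    filled = np.where(valid, first, 0)
    if valid.all():
        smoothed = median_filter(filled, size=3, mode="nearest")
    else:
        smoothed = filled
    interface_idx = np.where(valid, smoothed, nz)  # nz => whole column is water
    zi = np.arange(nz)[None, None, :]
    tissue = zi >= interface_idx[:, :, None]
    water = ~tissue
    interface_depth = np.where(valid, smoothed * dz, np.nan)
    return tissue, water, interface_depth


def extract_skin_shell(
    tissue_mask: np.ndarray,
    spacing: Sequence[float],
    thickness_mm: float = 0.5,
) -> np.ndarray:
    """The first ``thickness_mm`` of tissue below the interface, per column.

    Equivalent to eroding a Z-directed layer of ``round(thickness/dz)``
    voxels from the water-skin interface and subtracting the eroded volume
    from the tissue mask.
    """
    if not thickness_mm > 0:
        raise ValueError("thickness_mm must be > 0")
    dz = float(spacing[2])
    n = int(round(thickness_mm / dz))
    if n < 1:
        raise ValueError(
            f"shell thickness {thickness_mm} mm is below one voxel at dz={dz} mm; "
            "resample to a finer grid first"
        )
    depth_in_tissue = np.cumsum(tissue_mask, axis=2)
    return tissue_mask & (depth_in_tissue <= n)


def make_roi_mask(
    shape2d: tuple[int, int],
    spacing_xy: Sequence[float],
    kind: str = "full",
    size_mm: Optional[float] = None,
    center_mm: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Lateral ROI: ``square`` (edge length), ``circle`` (diameter) or ``full``.

    Pixel membership is evaluated at pixel centres.  An ROI extending beyond
    the lateral field of view is rejected with an overlap report.
    """
    nx, ny = shape2d
    dx, dy = float(spacing_xy[0]), float(spacing_xy[1])
    if kind == "full":
        return np.ones(shape2d, dtype=bool)
    if size_mm is None or not size_mm > 0:
        raise ValueError(f"{kind} ROI requires a positive size_mm")
    fx, fy = nx * dx, ny * dy
    cx, cy = center_mm if center_mm is not None else (fx / 2, fy / 2)
    half = size_mm / 2
    over_x = max(0.0, half - cx) + max(0.0, (cx + half) - fx)
    over_y = max(0.0, half - cy) + max(0.0, (cy + half) - fy)
    if over_x > dx / 2 or over_y > dy / 2:
        raise ValueError(
            f"ROI exceeds the {fx:g} x {fy:g} mm field by "
            f"({over_x:.2f}, {over_y:.2f}) mm"
        )
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    if kind == "square":
        return (np.abs(xx - cx) < half) & (np.abs(yy - cy) < half)
    if kind == "circle":
        return np.hypot(xx - cx, yy - cy) < half
    raise ValueError(f"unknown ROI kind {kind!r}")


def normalize_to_water(pa: Volume3D, water_mask: np.ndarray) -> Volume3D:
    """Divide the PA volume by its mean amplitude over the water region.

    Removes day-to-day laser-fluence fluctuations; the output has unit mean
    over water by construction.
    """
    if not water_mask.any():
        raise ValueError("water_mask is empty; no water reference available")
    ref = float(pa.values[water_mask].mean())
    if ref <= 0:
        raise ValueError(f"water reference amplitude must be positive, got {ref}")
    return pa.with_values(pa.values / ref)


def segment_session(
    us: Volume3D,
    thickness_mm: float = 0.5,
    roi: Optional[dict] = None,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> SkinSegmentation:
    """Full segmentation of one session's US volume."""
    tissue, water, interface = find_tissue_mask(us, method=method, threshold=threshold)
    shell = extract_skin_shell(tissue, us.spacing, thickness_mm)
    roi = roi or {"shape": "full"}
    roi_mask = make_roi_mask(
        us.shape[:2],
        us.spacing[:2],
        kind=roi.get("shape", "full"),
        size_mm=roi.get("size_mm"),
        center_mm=tuple(roi["center_mm"]) if "center_mm" in roi else None,
    )
    return SkinSegmentation(
        tissue_mask=tissue,
        skin_mask=shell,
        water_mask=water,
        interface_depth=interface,
        roi_mask_2d=roi_mask,
        n_excluded_columns=int(np.isnan(interface).sum()),
    )
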