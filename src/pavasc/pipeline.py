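"""End-to-end per-session processing: segmentation -> water normalization ->
unmixing -> vessel enhancement -> the three biomarkers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .biomarkers import pa_vasculature, total_hemoglobin_level, vascular_density
from .core import UNMIX_WAVELENGTHS, ImagingSession
from .segmentation import SkinSegmentation, normalize_to_water, segment_session
from .unmixing import ChromophoreMaps, unmix
from .vessels import VesselMap, enhance_vessels

__all__ = ["SessionResult", "process_session"]


@dataclass
class SessionResult:
    """Everything derived from one imaging session."""

    subject_id: str
    week: int
    score: int
    segmentation: SkinSegmentation
    chromophores: ChromophoreMaps
    vessel_map: VesselMap
    pa_vasculature: float
    vascular_density: float
    total_hemoglobin: float
    thb_map_2d: np.ndarray

    def record(self, group: str = "") -> dict:
        return {
            "subject": self.subject_id,
            "group": group,
            "week": self.week,
            "score": self.score,
            "pa_vasculature": self.pa_vasculature,
            "vascular_density": self.vascular_density,
            "total_hemoglobin": self.total_hemoglobin,
        }


def process_session(
    session: ImagingSession,
    roi: Optional[dict] = None,
    thickness_mm: float = 0.5,
    scale_vox: float = 4.0,
    tau: float = 0.5,
    band: tuple[float, float] = (-0.5, 0.5),
    use_suppressed: bool = True,
) -> SessionResult:
    """Run the full single-session pipeline and compute the biomarkers."""
    seg = segment_session(session.us, thickness_mm=thickness_mm, roi=roi)
    pa_norm = {
        wl: normalize_to_water(vol, seg.water_mask) for wl, vol in session.pa.items()
    }
    maps = unmix({wl: pa_norm[wl] for wl in UNMIX_WAVELENGTHS})
    vm = enhance_vessels(
        pa_norm[532], seg.skin_mask, scale_vox=scale_vox, tau=tau, band=band
    )
    density_map = vm.suppressed if use_suppressed else vm.enhanced
    from .spatial import flatten_thb  # local import to avoid cycle in docs builds

    return SessionResult(
        subject_id=session.subject_id,
        week=session.week,
        score=session.score.value,
        segmentation=seg,
        chromophores=maps,
        vessel_map=vm,
        pa_vasculature=pa_vasculature(pa_norm[532], seg.skin_mask, seg.roi_mask_2d),
        vascular_density=vascular_density(density_map, seg.roi_mask_2d),
        total_hemoglobin=total_hemoglobin_level(maps.thb, seg.skin_mask, seg.roi_mask_2d),
        thb_map_2d=flatten_thb(maps.thb, seg.skin_mask, seg.roi_mask_2d),
    )
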