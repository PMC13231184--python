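"""Per-session PA biomarkers and baseline-normalized longitudinal series.

Three biomarkers per session:

- *PA vasculature*: mean water-normalized 532 nm PA amplitude in the skin
  shell (laterally restricted to the ROI),
- *vascular density*: mean of the vertically-suppressed Jerman-enhanced
  vascular structure map over the ROI,
- *total hemoglobin*: mean Hb + HbO2 over skin shell and ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Volume3D

__all__ = [
    "BiomarkerSeries",
    "pa_vasculature",
    "vascular_density",
    "total_hemoglobin_level",
    "assemble_series",
    "series_to_frame",
]

BIOMARKER_NAMES = ("pa_vasculature", "vascular_density", "total_hemoglobin")


def _restrict(mask3d: np.ndarray, roi_mask_2d: np.ndarray) -> np.ndarray:
    """Broadcast the lateral ROI down all Z within a 3-D mask."""
    return mask3d & roi_mask_2d[:, :, None]


def pa_vasculature(
    pa532_normalized: Volume3D, skin_mask: np.ndarray, roi_mask_2d: np.ndarray
) -> float:
    """Mean water-normalized 532 nm PA amplitude in skin shell ∩ ROI."""
    sel = _restrict(skin_mask, roi_mask_2d)
    if not sel.any():
        raise ValueError("skin mask and ROI have an empty intersection")
    return float(pa532_normalized.values[sel].mean())


def vascular_density(suppressed_map: np.ndarray, roi_mask_2d: np.ndarray) -> float:
    """Mean of the suppressed enhanced vascular map over the ROI, in [0, 1]."""
    if suppressed_map.shape != roi_mask_2d.shape:
        raise ValueError("map and ROI must share a shape")
    if not roi_mask_2d.any():
        raise ValueError("ROI is empty")
    return float(suppressed_map[roi_mask_2d].mean())


def total_hemoglobin_level(
    thb: np.ndarray, skin_mask: np.ndarray, roi_mask_2d: np.ndarray
) -> float:
    """Mean total hemoglobin over skin shell ∩ ROI."""
    sel = _restrict(skin_mask, roi_mask_2d)
    if not sel.any():
        raise ValueError("skin mask and ROI have an empty intersection")
    return float(thb[sel].mean())


@dataclass
class BiomarkerSeries:
    """One subject's ordered week -> biomarker values, raw and normalized."""

    subject_id: str
    group: str
    weeks: list[int]
    raw: dict[str, list[float]]
    scores: list[int]
    normalized: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.weeks)
        if len(self.scores) != n:
            raise ValueError("weeks and scores lengths disagree")
        for name, vals in self.raw.items():
            if len(vals) != n:
                raise ValueError(f"weeks and {name} values lengths disagree")
        if not self.normalized:
            if self.weeks and self.weeks[0] != 0:
                raise ValueError(
                    f"subject {self.subject_id}: week 0 required for baseline normalization"
                )
            for name, vals in self.raw.items():
                base = vals[0]
                if not base > 0:
                    raise ValueError(
                        f"subject {self.subject_id}: zero/negative week-0 baseline for {name}"
                    )
                self.normalized[name] = [v / base for v in vals]


def assemble_series(
    records: Sequence[Mapping],
) -> list[BiomarkerSeries]:
    """Assemble per-session biomarker records into normalized series.

    ``records`` holds one mapping per session with keys ``subject``,
    ``group``, ``week``, ``score`` and one entry per biomarker name.
    Missing intermediate weeks stay as gaps (no imputation); a truncated
    series (dropout) is allowed, but week 0 must be present per subject.
    """
    by_subject: dict[str, list[Mapping]] = {}
    for rec in records:
        by_subject.setdefault(str(rec["subject"]), []).append(rec)
    out = []
    for sid, recs in by_subject.items():
        recs = sorted(recs, key=lambda r: r["week"])
        weeks = [int(r["week"]) for r in recs]
        if weeks[0] != 0:
            raise ValueError(f"subject {sid}: missing week-0 baseline session")
        raw = {
            name: [float(r[name]) for r in recs]
            for name in BIOMARKER_NAMES
            if name in recs[0]
        }
        out.append(
            BiomarkerSeries(
                subject_id=sid,
                group=str(recs[0].get("group", "")),
                weeks=weeks,
                raw=raw,
                scores=[int(r["score"]) for r in recs],
            )
        )
    return out


def series_to_frame(series: Sequence[BiomarkerSeries]) -> pd.DataFrame:
    """Tidy long-format table: subject, group, week, biomarker, raw,
    normalized, score."""
    rows = []
    for s in series:
        for name in s.raw:
            for i, w in enumerate(s.weeks):
                rows.append(
                    {
                        "subject": s.subject_id,
                        "group": s.group,
                        "week": w,
                        "biomarker": name,
                        "raw": s.raw[name][i],
                        "normalized": s.normalized[name][i],
                        "score": s.scores[i],
                    }
                )
    return pd.DataFrame(rows)
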