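"""Core domain types, volume I/O and resampling.

Axis convention: arrays are indexed ``(X, Y, Z)`` = (lateral, elevational,
depth), with Z increasing downward from the top of the water column into
tissue.  All physical quantities are millimetres.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import tifffile
import yaml
from scipy.ndimage import map_coordinates

__all__ = [
    "STUDY_WAVELENGTHS",
    "UNMIX_WAVELENGTHS",
    "Volume3D",
    "SkinScore",
    "ImagingSession",
    "SubjectEntry",
    "StudyManifest",
    "load_volume",
    "save_volume",
    "resample_isotropic",
]

#: The seven acquisition wavelengths (nm).
STUDY_WAVELENGTHS: tuple[int, ...] = (532, 700, 750, 800, 850, 900, 950)

#: Wavelengths entering spectral unmixing (532 nm excluded).
UNMIX_WAVELENGTHS: tuple[int, ...] = (700, 750, 800, 850, 900, 950)

_AXIS_NAMES = ("X", "Y", "Z")


@dataclass(frozen=True)
class Volume3D:
    """A 3-D non-negative scalar field with voxel spacing metadata.

    Parameters
    ----------
    values : ndarray
        3-D array of non-negative, finite voxel values, indexed (X, Y, Z).
    spacing : tuple of float
        Per-axis voxel size in mm; all entries strictly positive.
    modality : {"US", "PA"}
        Imaging modality.  PA volumes must carry ``wavelength_nm``;
        US volumes must not.
    wavelength_nm : float, optional
        Optical wavelength for PA volumes.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    wavelength_nm: Optional[float] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"not a 3-D volume: got {values.ndim} dimensions")
        bad = ~np.isfinite(values)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite voxel at index {idx}")
        if values.min() < 0:
            idx = tuple(int(i) for i in np.argwhere(values < 0)[0])
            raise ValueError(f"negative voxel value at index {idx}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValueError("spacing must have three entries (X, Y, Z)")
        for name, s in zip(_AXIS_NAMES, spacing):
            if not s > 0:
                raise ValueError(f"spacing along {name} must be > 0, got {s}")
        if self.modality not in ("US", "PA"):
            raise ValueError(f"modality must be 'US' or 'PA', got {self.modality!r}")
        if self.modality == "PA":
            if self.wavelength_nm is None or not self.wavelength_nm > 0:
                raise ValueError("PA volumes require a positive wavelength_nm")
        elif self.wavelength_nm is not None:
            raise ValueError("US volumes must not carry a wavelength")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent per axis (shape * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """Return a copy carrying ``values`` with the same metadata."""
        return Volume3D(values, self.spacing, self.modality, self.wavelength_nm)


_SCORE_LABELS = {
    5: "no visible skin damage",
    4: "minor spots or blisters with intact skin",
    3: "small skin dehiscence without implant exposure",
    2: "moderate dehiscence with slight implant exposure",
    1: "severe dehiscence with significant implant exposure",
}


@dataclass(frozen=True)
class SkinScore:
    """Ordinal 5-point skin-health score (5 intact ... 1 severe dehiscence)."""

    value: int

    def __post_init__(self) -> None:
        if not isinstance(self.value, (int, np.integer)) or isinstance(self.value, bool):
            raise ValueError(f"skin score must be an integer, got {self.value!r}")
        if int(self.value) not in _SCORE_LABELS:
            raise ValueError(f"skin score must be in 1..5, got {self.value}")
        object.__setattr__(self, "value", int(self.value))

    @property
    def label(self) -> str:
        return _SCORE_LABELS[self.value]


@dataclass
class ImagingSession:
    """One subject x one week: US volume, seven PA volumes, and a score."""

    subject_id: str
    week: int
    us: Volume3D
    pa: Mapping[float, Volume3D]
    score: SkinScore

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError("week must be non-negative")
        got = tuple(sorted(int(w) for w in self.pa))
        if got != tuple(sorted(STUDY_WAVELENGTHS)):
            raise ValueError(
                f"PA stack must contain exactly wavelengths {STUDY_WAVELENGTHS}, got {got}"
            )
        ref_shape, ref_spacing = self.us.shape, self.us.spacing
        for wl, vol in self.pa.items():
            if vol.shape != ref_shape or not np.allclose(vol.spacing, ref_spacing):
                raise ValueError(
                    f"PA volume at {wl} nm not co-registered with US "
                    f"(shape {vol.shape} vs {ref_shape})"
                )


@dataclass
class SubjectEntry:
    """One subject row of a study manifest."""

    subject_id: str
    group: str
    weeks: list[int]
    scores: dict[int, int] = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    files: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError(
                f"weeks for subject {self.subject_id} must be strictly increasing: {self.weeks}"
            )


@dataclass
class StudyManifest:
    """Binds subjects, groups, per-week scores and volume file paths."""

    subjects: list[SubjectEntry]
    spacing_mm: tuple[float, float, float] = (0.1, 0.1, 0.1)
    root: Optional[Path] = None

    def subject(self, subject_id: str) -> SubjectEntry:
        for entry in self.subjects:
            if entry.subject_id == subject_id:
                return entry
        raise KeyError(subject_id)

    def load_session(self, subject_id: str, week: int) -> "ImagingSession":
        """Load one subject-week session from the manifest's file paths."""
        entry = self.subject(subject_id)
        if week not in entry.files:
            raise KeyError(f"no session for subject {subject_id} at week {week}")
        rec = entry.files[week]
        root = self.root or Path(".")
        us = load_volume(root / rec["us"], spacing=self.spacing_mm, modality="US")
        pa = {
            float(wl): load_volume(
                root / p, spacing=self.spacing_mm, modality="PA", wavelength_nm=float(wl)
            )
            for wl, p in rec["pa"].items()
        }
        return ImagingSession(
            subject_id=subject_id,
            week=week,
            us=us,
            pa=pa,
            score=SkinScore(entry.scores[week]),
        )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "StudyManifest":
        """Load a manifest from a YAML or JSON file (schema in README)."""
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        subjects = []
        for sub in raw["subjects"]:
            sessions = sub.get("sessions", [])
            weeks = [int(s["week"]) for s in sessions]
            scores = {int(s["week"]): int(s["score"]) for s in sessions if "score" in s}
            files = {
                int(s["week"]): {"us": s.get("us"), "pa": s.get("pa", {})}
                for s in sessions
            }
            subjects.append(
                SubjectEntry(
                    subject_id=str(sub["id"]),
                    group=str(sub["group"]),
                    weeks=weeks,
                    scores=scores,
                    roi=sub.get("roi", {"shape": "full"}),
                    files=files,
                )
            )
        spacing = tuple(raw.get("spacing_mm", (0.1, 0.1, 0.1)))
        return cls(subjects=subjects, spacing_mm=spacing, root=path.parent)

    def to_file(self, path: str | os.PathLike) -> None:
        path = Path(path)
        raw = {
            "spacing_mm": list(self.spacing_mm),
            "subjects": [
                {
                    "id": sub.subject_id,
                    "group": sub.group,
                    "roi": sub.roi,
                    "sessions": [
                        {
                            "week": w,
                            **({"score": sub.scores[w]} if w in sub.scores else {}),
                            **sub.files.get(w, {}),
                        }
                        for w in sub.weeks
                    ],
                }
                for sub in self.subjects
            ],
        }
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(raw, fh, indent=2)
            else:
                yaml.safe_dump(raw, fh, sort_keys=False)


def load_volume(
    path: str | os.PathLike,
    spacing: Optional[Sequence[float]] = None,
    modality: str = "US",
    wavelength_nm: Optional[float] = None,
) -> Volume3D:
    """Load a 3-D volume from NIfTI (.nii/.nii.gz) or multi-page TIFF.

    NIfTI spacing is taken from the header unless ``spacing`` is given;
    TIFF requires an explicit ``spacing``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float64)
        if spacing is None:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif name.endswith((".tif", ".tiff")):
        values = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        if values.ndim == 3:
            # TIFF pages stack along the first axis = Z; reorder to (X, Y, Z)
            values = np.moveaxis(values, 0, -1)
        if spacing is None:
            raise ValueError("TIFF volumes require explicit spacing metadata")
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if values.ndim != 3:
        raise ValueError(f"not a 3-D volume: {path} has {values.ndim} dimensions")
    return Volume3D(values, tuple(spacing), modality, wavelength_nm)


def save_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Save a volume as NIfTI (spacing in the header) or multi-page TIFF."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), np.moveaxis(volume.values, -1, 0))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def resample_isotropic(volume: Volume3D, target_mm: float = 0.1) -> Volume3D:
    """Resample to isotropic voxels by trilinear interpolation.

    Voxel values are treated as samples at voxel centres; edges are handled
    by clamping to the border value.  The physical extent is preserved to
    within one voxel.
    """
    if not target_mm > 0:
        raise ValueError("target_mm must be > 0")
    if np.allclose(volume.spacing, target_mm):
        return volume
    for name, n in zip(_AXIS_NAMES, volume.shape):
        if n == 1:
            raise ValueError(f"cannot resample degenerate axis {name} (length 1)")
    new_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(volume.shape, volume.spacing)
    )
    grids = [
        (np.arange(m) + 0.5) * target_mm / s - 0.5
        for m, s in zip(new_shape, volume.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = map_coordinates(volume.values, coords, order=1, mode="nearest")
    out = np.clip(out, 0.0, None)
    return Volume3D(out, (target_mm,) * 3, volume.modality, volume.wavelength_nm)
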