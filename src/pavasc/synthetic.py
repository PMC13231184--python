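"""Synthetic US/PA phantoms and longitudinal cohorts with known ground truth.

Every downstream stage of the pipeline is testable against these generators:
an anechoic water layer above a hyperechoic curved tissue interface, tubular
vessels with wavelength-dependent photoacoustic contrast from Hb/HbO2,
vertical implant-surface ridge artifacts, and exposed-vs-healthy longitudinal
trajectories in which biomarker decline leads score decline by a configurable
number of weeks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    STUDY_WAVELENGTHS,
    ImagingSession,
    SkinScore,
    StudyManifest,
    SubjectEntry,
    Volume3D,
)

__all__ = [
    "Vessel",
    "Ridge",
    "PhantomSpec",
    "CohortSpec",
    "tabulated_extinction",
    "generate_us_volume",
    "concentration_fields",
    "generate_pa_stack",
    "generate_biomarker_cohort",
    "generate_longitudinal_cohort",
    "lagged_series_pair",
    "generate_dehiscence_scenario",
    "default_phantom",
]

# ---------------------------------------------------------------------------
# Extinction spectra


def _load_extinction_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = importlib.resources.files("pavasc.data") / "hb_extinction.csv"
    with importlib.resources.as_file(ref) as path:
        arr = np.loadtxt(path, delimiter=",", skiprows=5)
    return arr[:, 0], arr[:, 1], arr[:, 2]


_EXTINCTION_CACHE: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None


def tabulated_extinction(chromophore: str, wavelength_nm: float) -> float:
    """Molar extinction coefficient (cm^-1/M) of Hb or HbO2.

    Values come from the bundled compilation adapted from S. Prahl's
    hemoglobin spectra tables (Oregon Medical Laser Center), linearly
    interpolated between tabulated wavelengths.

    Raises
    ------
    ValueError
        If the wavelength falls outside the bundled 500-1000 nm range or
        the chromophore name is unknown.
    """
    global _EXTINCTION_CACHE
    if _EXTINCTION_CACHE is None:
        _EXTINCTION_CACHE = _load_extinction_table()
    wl, hbo2, hb = _EXTINCTION_CACHE
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside bundled table "
            f"range [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    key = chromophore.lower()
    if key == "hb":
        return float(np.interp(wavelength_nm, wl, hb))
    if key == "hbo2":
        return float(np.interp(wavelength_nm, wl, hbo2))
    raise ValueError(f"unknown chromophore {chromophore!r}; expected 'Hb' or 'HbO2'")


# ---------------------------------------------------------------------------
# Phantom specification


@dataclass(frozen=True)
class Vessel:
    """A straight tubular vessel following the skin surface.

    The centerline runs laterally from ``p0_mm`` to ``p1_mm`` at a constant
    depth below the local skin interface.  The cross-section is Gaussian with
    sigma = radius / 2.
    """

    p0_mm: tuple[float, float]
    p1_mm: tuple[float, float]
    depth_mm: float = 0.25
    radius_mm: float = 0.2
    c_hb: float = 0.0
    c_hbo2: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("vessel radius must be > 0")
        if self.c_hb < 0 or self.c_hbo2 < 0:
            raise ValueError("chromophore concentrations must be >= 0")


@dataclass(frozen=True)
class Ridge:
    """A vertical (Y-oriented) implant-surface ridge artifact.

    Rendered as a depth-extended sheet through the tissue at lateral
    position ``x_mm``, spanning ``y0_mm``..``y1_mm``.
    """

    x_mm: float
    y0_mm: float
    y1_mm: float
    amplitude: float = 1.0
    width_mm: float = 0.2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise of a single US/PA phantom."""

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing_mm: float = 0.1
    surface_depth_mm: float = 1.5
    #: optional implant mound: (center_x, center_y, height_mm, sigma_mm);
    #: raises the skin surface toward the water by a Gaussian bump.
    bump: Optional[tuple[float, float, float, float]] = None
    skin_thickness_mm: float = 0.5
    vessels: tuple[Vessel, ...] = ()
    ridges: tuple[Ridge, ...] = ()
    tissue_echogenicity: float = 1.0
    noise_us: float = 0.0
    noise_pa: float = 0.0
    water_pa_amplitude: float = 0.05
    fluence: Mapping[float, float] = field(
        default_factory=lambda: {wl: 1.0 for wl in STUDY_WAVELENGTHS}
    )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing_mm for n in self.shape)  # type: ignore[return-value]

    def lateral_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (mm) of the lateral grid."""
        nx, ny, _ = self.shape
        x = (np.arange(nx) + 0.5) * self.spacing_mm
        y = (np.arange(ny) + 0.5) * self.spacing_mm
        return x, y

    def depth_coords(self) -> np.ndarray:
        return (np.arange(self.shape[2]) + 0.5) * self.spacing_mm

    def surface_depth_map(self) -> np.ndarray:
        """Skin interface depth z0(x, y) in mm, shape (nx, ny)."""
        x, y = self.lateral_coords()
        z0 = np.full((self.shape[0], self.shape[1]), float(self.surface_depth_mm))
        if self.bump is not None:
            cx, cy, height, sigma = self.bump
            xx, yy = np.meshgrid(x, y, indexing="ij")
            z0 = z0 - height * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        return z0

    # -- ground-truth masks --------------------------------------------------

    def truth_masks(self) -> dict[str, np.ndarray]:
        """Exact water / tissue / skin-shell masks implied by the geometry."""
        z0 = self.surface_depth_map()[:, :, None]
        zc = self.depth_coords()[None, None, :]
        tissue = zc >= z0
        shell = tissue & (zc < z0 + self.skin_thickness_mm)
        return {"water": ~tissue, "tissue": tissue, "skin": shell}

    def vessel_footprint(self, threshold: float = 0.5) -> np.ndarray:
        """Lateral mask of pixels whose Gaussian vessel profile >= threshold."""
        x, y = self.lateral_coords()
        xx, yy = np.meshgrid(x, y, indexing="ij")
        out = np.zeros(xx.shape, dtype=bool)
        for v in self.vessels:
            d = _dist_to_segment(xx, yy, v.p0_mm, v.p1_mm)
            out |= np.exp(-(d**2) / (2 * (v.radius_mm / 2) ** 2)) >= threshold
        return out


def _dist_to_segment(
    xx: np.ndarray, yy: np.ndarray, p0: Sequence[float], p1: Sequence[float]
) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        return np.hypot(xx - p0[0], yy - p0[1])
    t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1]))


def _check_surface(spec: PhantomSpec) -> np.ndarray:
    z0 = spec.surface_depth_map()
    if (z0 <= 0).any() or (z0 >= spec.extent_mm[2]).any():
        raise ValueError("skin surface leaves the grid (z0 outside (0, depth extent))")
    return z0


# ---------------------------------------------------------------------------
# Volume generation


def generate_us_volume(spec: PhantomSpec, seed: int = 0) -> Volume3D:
    """Render the US phantom: anechoic water above a hyperechoic interface."""
    z0 = _check_surface(spec)[:, :, None]
    zc = spec.depth_coords()[None, None, :]
    values = np.where(zc >= z0, spec.tissue_echogenicity, 0.0)
    values = np.broadcast_to(values, spec.shape).astype(np.float64)
    if spec.noise_us > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.noise_us, spec.shape)
    return Volume3D(np.clip(values, 0.0, None), (spec.spacing_mm,) * 3, "US")


def concentration_fields(
    spec: PhantomSpec,
    vessel_scales: Optional[Sequence[float]] = None,
    scale_map: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise (C_Hb, C_HbO2) fields from the vessel list.

    ``vessel_scales`` multiplies each vessel's concentrations (longitudinal
    decline); ``scale_map`` is an optional lateral (nx, ny) map applied to
    both fields (localized dehiscence-site drops).
    """
    z0 = _check_surface(spec)
    x, y = spec.lateral_coords()
    xx, yy = np.meshgrid(x, y, indexing="ij")
    zc = spec.depth_coords()[None, None, :]
    c_hb = np.zeros(spec.shape, dtype=np.float64)
    c_hbo2 = np.zeros(spec.shape, dtype=np.float64)
    scales = vessel_scales if vessel_scales is not None else [1.0] * len(spec.vessels)
    if len(scales) != len(spec.vessels):
        raise ValueError("vessel_scales must match the number of vessels")
    for v, s in zip(spec.vessels, scales):
        lat2 = _dist_to_segment(xx, yy, v.p0_mm, v.p1_mm) ** 2
        vert2 = (zc - (z0 + v.depth_mm)[:, :, None]) ** 2
        profile = np.exp(-(lat2[:, :, None] + vert2) / (2 * (v.radius_mm / 2) ** 2))
        c_hb += s * v.c_hb * profile
        c_hbo2 += s * v.c_hbo2 * profile
    if scale_map is not None:
        c_hb *= scale_map[:, :, None]
        c_hbo2 *= scale_map[:, :, None]
    # chromophores exist only in tissue: clip Gaussian tails above the skin
    tissue = zc >= z0[:, :, None]
    c_hb *= tissue
    c_hbo2 *= tissue
    return c_hb, c_hbo2


def generate_pa_stack(
    spec: PhantomSpec,
    seed: int = 0,
    vessel_scales: Optional[Sequence[float]] = None,
    scale_map: Optional[np.ndarray] = None,
) -> dict[float, Volume3D]:
    """Render the seven-wavelength PA stack.

    Noiseless vessel amplitude at wavelength ``wl`` is
    ``fluence(wl) * (eps_Hb(wl) * C_Hb + eps_HbO2(wl) * C_HbO2)``; ridge
    artifacts are depth-extended sheets added within the tissue, and water
    voxels carry a small constant reference amplitude.
    """
    wavelengths = tuple(sorted(spec.fluence))
    if wavelengths != tuple(sorted(STUDY_WAVELENGTHS)):
        raise ValueError(f"fluence must cover exactly the wavelengths {STUDY_WAVELENGTHS}")
    z0 = _check_surface(spec)
    c_hb, c_hbo2 = concentration_fields(spec, vessel_scales, scale_map)
    zc = spec.depth_coords()[None, None, :]
    tissue = zc >= z0[:, :, None]
    water = ~tissue

    ridge_field = np.zeros(spec.shape[:2], dtype=np.float64)
    x, yv = spec.lateral_coords()
    xx, yy = np.meshgrid(x, yv, indexing="ij")
    for r in spec.ridges:
        lateral = np.exp(-((xx - r.x_mm) ** 2) / (2 * (r.width_mm / 2) ** 2))
        lateral = np.where((yy >= r.y0_mm) & (yy <= r.y1_mm), lateral, 0.0)
        ridge_field += r.amplitude * lateral

    rng = np.random.default_rng(seed)
    stack: dict[float, Volume3D] = {}
    for wl in STUDY_WAVELENGTHS:
        eps_hb = tabulated_extinction("Hb", wl)
        eps_hbo2 = tabulated_extinction("HbO2", wl)
        fl = float(spec.fluence[wl])
        values = fl * (eps_hb * c_hb + eps_hbo2 * c_hbo2)
        values = values + fl * ridge_field[:, :, None] * tissue
        values = values + spec.water_pa_amplitude * water
        if spec.noise_pa > 0:
            values = values + rng.normal(0.0, spec.noise_pa, spec.shape)
        stack[wl] = Volume3D(
            np.clip(values, 0.0, None), (spec.spacing_mm,) * 3, "PA", wavelength_nm=wl
        )
    return stack


def default_phantom(
    shape: tuple[int, int, int] = (64, 64, 40),
    spacing_mm: float = 0.1,
    noise_us: float = 0.0,
    noise_pa: float = 0.0,
    n_vessels: int = 3,
    c_hb: float = 5e-4,
    c_hbo2: float = 5e-4,
) -> PhantomSpec:
    """A small phantom with horizontal vessels spread across the field."""
    ex, ey, _ = (n * spacing_mm for n in shape)
    vessels = tuple(
        Vessel(
            p0_mm=(0.05 * ex, ey * (i + 1) / (n_vessels + 1)),
            p1_mm=(0.95 * ex, ey * (i + 1) / (n_vessels + 1)),
            depth_mm=0.25,
            radius_mm=2 * spacing_mm,
            c_hb=c_hb,
            c_hbo2=c_hbo2,
        )
        for i in range(n_vessels)
    )
    return PhantomSpec(
        shape=shape,
        spacing_mm=spacing_mm,
        surface_depth_mm=min(1.5, 0.4 * shape[2] * spacing_mm),
        vessels=vessels,
        noise_us=noise_us,
        noise_pa=noise_pa,
    )


# ---------------------------------------------------------------------------
# Longitudinal cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal exposed-vs-healthy cohort design.

    Exposed subjects' biomarkers decline geometrically from ``onset_week``,
    reaching ``decline_fraction`` of baseline at the final week; healthy
    subjects stay flat up to multiplicative jitter.  Scores decline stepwise
    from 5 starting ``lag_weeks`` after the biomarker onset.
    """

    n_healthy: int = 11
    n_exposed: int = 5
    weeks: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12)
    decline_fraction: float = 0.5
    onset_week: int = 2
    lag_weeks: int = 4
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        if not 0 <= self.decline_fraction <= 1:
            raise ValueError("decline_fraction must be in [0, 1]")
        step = self.weeks[1] - self.weeks[0]
        if self.lag_weeks % step != 0:
            raise ValueError(
                f"lag_weeks must be a multiple of the sampling interval ({step} weeks)"
            )

    @property
    def step_weeks(self) -> int:
        return self.weeks[1] - self.weeks[0]

    def decline(self, week: float) -> float:
        """Multiplicative decline d(w) for the exposed group."""
        last = self.weeks[-1]
        if week <= self.onset_week or self.decline_fraction == 1.0:
            return 1.0
        frac = (min(week, last) - self.onset_week) / (last - self.onset_week)
        return float(self.decline_fraction**frac)

    def score(self, week: float, exposed: bool) -> int:
        """Stepwise 5 -> 1 integer score with the configured lag."""
        if not exposed or self.decline_fraction == 1.0:
            return 5
        onset = self.onset_week + self.lag_weeks
        if week < onset:
            return 5
        steps = 1 + int((week - onset) // self.step_weeks)
        return max(1, 5 - steps)


_BIOMARKERS = ("pa_vasculature", "vascular_density", "total_hemoglobin")


def generate_biomarker_cohort(
    cohort: CohortSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Simulate biomarker *series* directly (no volume rendering).

    Returns a tidy long-format frame with columns ``subject, group, week,
    score, biomarker, raw, normalized`` plus a ground-truth record.  Used for
    statistical simulation studies where rendering volumes per replicate
    would be prohibitive.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"subjects": {}, "lag_weeks": cohort.lag_weeks}
    for group, n in (("healthy", cohort.n_healthy), ("exposed", cohort.n_exposed)):
        for i in range(n):
            sid = f"{group[0]}{i + 1:02d}"
            exposed = group == "exposed"
            declines = [cohort.decline(w) if exposed else 1.0 for w in cohort.weeks]
            truth["subjects"][sid] = {"group": group, "decline": dict(zip(cohort.weeks, declines))}
            for biomarker in _BIOMARKERS:
                raw = np.array(declines) * (
                    1.0 + cohort.noise_sigma * rng.standard_normal(len(cohort.weeks))
                )
                raw = np.clip(raw, 1e-9, None)
                normalized = raw / raw[0]
                for w, r, v in zip(cohort.weeks, raw, normalized):
                    rows.append(
                        {
                            "subject": sid,
                            "group": group,
                            "week": w,
                            "score": cohort.score(w, exposed),
                            "biomarker": biomarker,
                            "raw": float(r),
                            "normalized": float(v),
                        }
                    )
    return pd.DataFrame(rows), truth


def generate_longitudinal_cohort(
    cohort: CohortSpec,
    seed: int = 0,
    phantom: Optional[PhantomSpec] = None,
) -> tuple[StudyManifest, dict[tuple[str, int], ImagingSession], dict]:
    """Render a full imaging cohort: one phantom session per subject-week.

    Exposed subjects' vessel concentrations are scaled by the cohort decline
    d(w) (with multiplicative jitter of ``noise_sigma``); healthy subjects
    stay constant up to jitter.  Ground truth records the true per-week
    decline fraction and the configured lag per subject.
    """
    base = phantom if phantom is not None else default_phantom()
    rng = np.random.default_rng(seed)
    sessions: dict[tuple[str, int], ImagingSession] = {}
    entries: list[SubjectEntry] = []
    truth: dict = {"subjects": {}, "lag_weeks": cohort.lag_weeks, "phantom": base}
    for group, n in (("healthy", cohort.n_healthy), ("exposed", cohort.n_exposed)):
        for i in range(n):
            sid = f"{group[0]}{i + 1:02d}"
            exposed = group == "exposed"
            declines, scores = {}, {}
            for w in cohort.weeks:
                d = cohort.decline(w) if exposed else 1.0
                jitter = 1.0 + cohort.noise_sigma * rng.standard_normal()
                scale = max(d * jitter, 1e-9)
                declines[w] = d
                scores[w] = cohort.score(w, exposed)
                sub_seed = int(rng.integers(0, 2**31))
                us = generate_us_volume(base, seed=sub_seed)
                pa = generate_pa_stack(
                    base, seed=sub_seed + 1, vessel_scales=[scale] * len(base.vessels)
                )
                sessions[(sid, w)] = ImagingSession(
                    subject_id=sid, week=w, us=us, pa=pa, score=SkinScore(scores[w])
                )
            entries.append(
                SubjectEntry(
                    subject_id=sid,
                    group=group,
                    weeks=list(cohort.weeks),
                    scores=scores,
                    roi={"shape": "full"},
                )
            )
            truth["subjects"][sid] = {"group": group, "decline": declines}
    manifest = StudyManifest(subjects=entries, spacing_mm=(base.spacing_mm,) * 3)
    return manifest, sessions, truth


# ---------------------------------------------------------------------------
# Series-level helpers for lag analysis


def lagged_series_pair(
    lead_weeks: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    weeks: Sequence[int] = (0, 2, 4, 6, 8, 10, 12),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A biomarker series and a score-like series it *leads* by ``lead_weeks``.

    The underlying trajectory is a smooth sigmoidal decline; the score-like
    series is the same trajectory delayed by ``lead_weeks`` (so the expected
    cross-correlation lag is ``-lead_weeks``).  ``noise_sigma`` is expressed
    as a fraction of the trajectory's dynamic range and is applied
    independently to both series.
    """
    weeks = np.asarray(weeks, dtype=float)

    def traj(w: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((w - 6.0) / 1.0))

    biomarker = traj(weeks)
    score_like = traj(weeks - lead_weeks)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rng_range = float(biomarker.max() - biomarker.min())
        biomarker = biomarker + noise_sigma * rng_range * rng.standard_normal(len(weeks))
        score_like = score_like + noise_sigma * rng_range * rng.standard_normal(len(weeks))
    return weeks, biomarker, score_like


# ---------------------------------------------------------------------------
# Dehiscence-site scenario


def generate_dehiscence_scenario(
    seed: int = 0,
    shape: tuple[int, int, int] = (80, 80, 30),
    spacing_mm: float = 0.1,
    weeks: Sequence[int] = (2, 4, 6, 8, 10, 12),
    drop_week: int = 8,
    drop_fraction: float = 0.6,
    site_radius_mm: float = 1.6,
    noise_sigma: float = 0.05,
) -> dict:
    """Localized hemoglobin drop preceding a score drop by one interval.

    Vessels crossing a central disc lose ``drop_fraction`` of their
    concentration inside the disc from ``drop_week`` on; the skin score drops
    one sampling interval (2 weeks by default) later.  Returns per-week PA
    stacks and US volumes, the scenario phantom, the score series and the
    ground-truth lateral at-risk region: the hemoglobin-bearing area within
    the disc, i.e. where the noiseless baseline THb map (smoothed at the
    default 0.3 mm analysis scale) exceeds 10% of its in-disc maximum.
    """
    from scipy.ndimage import gaussian_filter  # local: keep module deps light

    base = default_phantom(shape=shape, spacing_mm=spacing_mm, n_vessels=4)
    base = replace(
        base,
        vessels=tuple(replace(v, radius_mm=0.4) for v in base.vessels),
        noise_pa=noise_sigma * 0.5,
    )
    ex, ey, _ = base.extent_mm
    cx, cy = ex / 2, ey / 2
    x, y = base.lateral_coords()
    xx, yy = np.meshgrid(x, y, indexing="ij")
    disc = np.hypot(xx - cx, yy - cy) <= site_radius_mm
    drop_map = np.where(disc, 1.0 - drop_fraction, 1.0)

    weeks = tuple(int(w) for w in weeks)
    step = weeks[1] - weeks[0]
    score_drop_week = drop_week + step
    rng = np.random.default_rng(seed)
    stacks, us_volumes, scores = {}, {}, {}
    for w in weeks:
        scale_map = drop_map if w >= drop_week else None
        sub_seed = int(rng.integers(0, 2**31))
        stacks[w] = generate_pa_stack(base, seed=sub_seed, scale_map=scale_map)
        us_volumes[w] = generate_us_volume(base, seed=sub_seed + 1)
        scores[w] = 5 if w < score_drop_week else max(1, 5 - (1 + (w - score_drop_week) // step))

    c_hb, c_hbo2 = concentration_fields(base)
    thb_baseline = (c_hb + c_hbo2).max(axis=2)
    smoothed = gaussian_filter(thb_baseline, 0.3 / spacing_mm, mode="reflect")
    truth_region = disc & (smoothed >= 0.1 * smoothed[disc].max())
    return {
        "phantom": base,
        "weeks": weeks,
        "pa_stacks": stacks,
        "us_volumes": us_volumes,
        "scores": scores,
        "drop_week": drop_week,
        "score_drop_week": score_drop_week,
        "truth_region": truth_region,
    }
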