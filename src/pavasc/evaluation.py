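"""Simulation studies used for validation: unmixing oracle error,
segmentation recovery, suppression selectivity, lag-recovery rates, LME
power / type-I rates, and spatial localization scores.

Each function recomputes its quantity from scratch by running the pipeline
on freshly generated synthetic data.
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .core import UNMIX_WAVELENGTHS, Volume3D
from .segmentation import segment_session
from .spatial import flatten_thb, localization_score, weekly_reduction_masks
from .stats import fit_group_time_interaction, xcorr_lag
from .unmixing import extinction_matrix, unmix
from .vessels import frangi_direction, jerman_vesselness, suppress_vertical

__all__ = [
    "unmixing_oracle_error",
    "segmentation_dice_study",
    "suppression_selectivity",
    "lag_recovery_study",
    "interaction_power_study",
    "interaction_null_study",
    "spatial_localization_study",
]


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0


def unmixing_oracle_error(n_voxels: int = 10_000, seed: int = 0) -> float:
    """Max relative recovery error on a noiseless stack with known truth."""
    rng = np.random.default_rng(seed)
    A = extinction_matrix()
    C = rng.uniform(0.1, 1.0, (n_voxels, 2))
    P = C @ A.T
    shape = (n_voxels, 1, 1)
    stack = {
        wl: Volume3D(P[:, i].reshape(shape), (0.1,) * 3, "PA", wl)
        for i, wl in enumerate(UNMIX_WAVELENGTHS)
    }
    maps = unmix(stack)
    rec = np.stack([maps.hb.ravel(), maps.hbo2.ravel()], axis=1)
    return float(np.max(np.abs(rec - C) / C))


def segmentation_dice_study(
    n_seeds: int = 20, noise_sigma: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Skin-shell Dice vs generator truth, noiseless and at 5% noise."""
    clean = syn.default_phantom(noise_us=0.0)
    truth = clean.truth_masks()["skin"]
    seg = segment_session(syn.generate_us_volume(clean, seed=seed))
    noiseless = _dice(seg.skin_mask, truth)
    noisy_spec = syn.default_phantom(noise_us=noise_sigma)
    dices = []
    for k in range(n_seeds):
        us = syn.generate_us_volume(noisy_spec, seed=seed + 1 + k)
        dices.append(_dice(segment_session(us).skin_mask, truth))
    return {"noiseless_dice": noiseless, "noisy_dice_min": float(min(dices)),
            "noisy_dice_mean": float(np.mean(dices))}


def suppression_selectivity(n: int = 128) -> dict[str, float]:
    """Fraction of ridge vesselness removed / tube vesselness retained on a
    two-structure image, plus the same after a 90-degree rotation."""
    x = np.arange(n, dtype=float)
    img = np.tile(np.exp(-((x - 40) ** 2) / (2 * 2.0**2))[None, :], (n, 1))
    img = img + np.exp(-((x - 90) ** 2) / (2 * 2.0**2))[:, None] * (x >= 60)[None, :]
    tube = np.zeros((n, n), bool)
    tube[:, 28:53] = True
    ridge = np.zeros((n, n), bool)
    ridge[78:103, 60:] = True
    ridge &= ~tube

    def run(image, tube_m, ridge_m):
        e = jerman_vesselness(image, 4.0)
        s = suppress_vertical(e, frangi_direction(image, 4.0))
        return s[tube_m].sum() / e[tube_m].sum(), 1 - s[ridge_m].sum() / e[ridge_m].sum()

    kept, removed = run(img, tube, ridge)
    kept_rot, removed_rot = run(np.rot90(img), np.rot90(ridge), np.rot90(tube))
    return {
        "tube_retained": float(kept),
        "ridge_removed": float(removed),
        "rotated_old_ridge_retained": float(kept_rot),
        "rotated_old_tube_removed": float(removed_rot),
    }


def lag_recovery_study(
    n_seeds: int = 200,
    lead_weeks: int = 4,
    noise_sigma: float = 0.10,
    tol_weeks: float = 2.0,
    seed: int = 0,
) -> dict[str, float]:
    """Noiseless exactness and noisy recovery rate of the injected lead."""
    w, b, s = syn.lagged_series_pair(lead_weeks, 0.0)
    clean = xcorr_lag(w, b, s)
    hits = 0
    for k in range(n_seeds):
        w, b, s = syn.lagged_series_pair(lead_weeks, noise_sigma, seed=seed + k)
        res = xcorr_lag(w, b, s)
        hits += abs(res.lag_weeks + lead_weeks) <= tol_weeks
    return {
        "noiseless_lag_weeks": float(clean.lag_weeks),
        "noiseless_coefficient": float(clean.coefficient),
        "noisy_recovery_rate": hits / n_seeds,
    }


def interaction_power_study(
    n_replicates: int = 100, seed: int = 0
) -> dict[str, float]:
    """Per-biomarker rate of p < 0.05 for the default declining cohort."""
    cohort = syn.CohortSpec()
    rates = {}
    for biomarker in ("pa_vasculature", "vascular_density", "total_hemoglobin"):
        hits = 0
        for k in range(n_replicates):
            df, _ = syn.generate_biomarker_cohort(cohort, seed=seed + k)
            res = fit_group_time_interaction(df, biomarker)
            hits += res.p_value < 0.05
        rates[biomarker] = hits / n_replicates
    return rates


def interaction_null_study(n_replicates: int = 200, seed: int = 0) -> float:
    """Empirical false-positive rate when both groups are flat."""
    null = syn.CohortSpec(decline_fraction=1.0)
    fps = 0
    for k in range(n_replicates):
        df, _ = syn.generate_biomarker_cohort(null, seed=seed + k)
        fps += fit_group_time_interaction(df, "pa_vasculature").p_value < 0.05
    return fps / n_replicates


def spatial_localization_study(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Dice of pre-drop reduction-mask union vs the scenario truth region."""
    dices = []
    for k in range(n_seeds):
        sc = syn.generate_dehiscence_scenario(seed=seed + k)
        roi = np.ones(sc["phantom"].shape[:2], bool)
        maps = {}
        for w in sc["weeks"]:
            seg = segment_session(sc["us_volumes"][w])
            thb = unmix(sc["pa_stacks"][w]).thb
            maps[w] = flatten_thb(thb, seg.skin_mask, roi)
        masks = weekly_reduction_masks(maps, roi, skip_first_pair=False)
        pre = [m for m in masks if m.week_pair[1] <= sc["score_drop_week"]]
        dices.append(localization_score(pre, sc["truth_region"])["dice"])
    return {"dice_min": float(min(dices)), "dice_mean": float(np.mean(dices))}
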