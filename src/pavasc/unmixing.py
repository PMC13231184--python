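"""Voxelwise linear spectral unmixing of Hb and HbO2.

Per voxel the six 700-950 nm PA amplitudes are solved for non-negative
chromophore concentrations by least squares.  With only two chromophores the
non-negative solution has a closed form: take the unconstrained solution if
it is feasible, otherwise the best of the two single-chromophore boundary
solutions (clipped at zero).  This is exactly the NNLS optimum and is fully
vectorized over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import UNMIX_WAVELENGTHS, Volume3D
from .synthetic import tabulated_extinction

__all__ = ["ChromophoreMaps", "extinction_matrix", "unmix", "oxygen_saturation"]


@dataclass
class ChromophoreMaps:
    """Voxelwise Hb / HbO2 concentrations (arbitrary units) and derivatives."""

    hb: np.ndarray
    hbo2: np.ndarray
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.hb.shape != self.hbo2.shape:
            raise ValueError("Hb and HbO2 grids must share a shape")
        if (self.hb < 0).any() or (self.hbo2 < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def thb(self) -> np.ndarray:
        """Total hemoglobin, Hb + HbO2 exactly."""
        return self.hb + self.hbo2


def extinction_matrix(
    wavelengths: Sequence[float] = UNMIX_WAVELENGTHS,
    fluence: Optional[Mapping[float, float]] = None,
) -> np.ndarray:
    """Extinction matrix A with columns (Hb, HbO2), optionally fluence-weighted."""
    rows = []
    for wl in wavelengths:
        f = float(fluence[wl]) if fluence is not None else 1.0
        rows.append(
            [f * tabulated_extinction("Hb", wl), f * tabulated_extinction("HbO2", wl)]
        )
    return np.asarray(rows, dtype=np.float64)


def _nnls_two_column(A: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Exact NNLS for a two-column design, vectorized over rows of P."""
    a1, a2 = A[:, 0], A[:, 1]
    g11, g22, g12 = a1 @ a1, a2 @ a2, a1 @ a2
    b1, b2 = P @ a1, P @ a2
    det = g11 * g22 - g12**2
    # unconstrained least-squares solution
    c1 = (g22 * b1 - g12 * b2) / det
    c2 = (g11 * b2 - g12 * b1) / det
    feasible = (c1 >= 0) & (c2 >= 0)
    # boundary candidates: one chromophore at a time, clipped at zero
    s1 = np.clip(b1 / g11, 0.0, None)
    s2 = np.clip(b2 / g22, 0.0, None)
    # residual^2 up to the constant |p|^2 term
    r1 = g11 * s1**2 - 2 * b1 * s1
    r2 = g22 * s2**2 - 2 * b2 * s2
    use1 = r1 <= r2
    out = np.empty(P.shape[:-1] + (2,), dtype=np.float64)
    out[..., 0] = np.where(feasible, c1, np.where(use1, s1, 0.0))
    out[..., 1] = np.where(feasible, c2, np.where(use1, 0.0, s2))
    return out


def unmix(
    pa_stack: Mapping[float, Volume3D],
    spectra: Optional[np.ndarray] = None,
    fluence: Optional[Mapping[float, float]] = None,
) -> ChromophoreMaps:
    """Estimate voxelwise (C_Hb, C_HbO2) from the six 700-950 nm volumes.

    Parameters
    ----------
    pa_stack : mapping of wavelength -> Volume3D
        Must contain all six unmixing wavelengths (extra wavelengths, e.g.
        532 nm, are ignored), co-registered.
    spectra : ndarray of shape (6, 2), optional
        Extinction matrix with columns (Hb, HbO2); defaults to the bundled
        table.  Must be full rank.
    """
    missing = [wl for wl in UNMIX_WAVELENGTHS if wl not in pa_stack]
    if missing:
        raise ValueError(f"missing wavelengths for unmixing: {missing}")
    A = spectra if spectra is not None else extinction_matrix(UNMIX_WAVELENGTHS, fluence)
    A = np.asarray(A, dtype=np.float64)
    if A.shape != (len(UNMIX_WAVELENGTHS), 2):
        raise ValueError(f"spectra must be {len(UNMIX_WAVELENGTHS)} x 2, got {A.shape}")
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("extinction matrix is rank-deficient")
    vols = [pa_stack[wl] for wl in UNMIX_WAVELENGTHS]
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape or not np.allclose(v.spacing, vols[0].spacing):
            raise ValueError("unmixing volumes are not co-registered")
    P = np.stack([v.values.reshape(-1) for v in vols], axis=-1)
    C = _nnls_two_column(A, P)
    return ChromophoreMaps(
        hb=C[..., 0].reshape(shape),
        hbo2=C[..., 1].reshape(shape),
        spacing=vols[0].spacing,
    )


def oxygen_saturation(
    maps: ChromophoreMaps, thb_floor: Optional[float] = None
) -> np.ndarray:
    """sO2 = HbO2 / THb where THb >= floor, NaN (masked) elsewhere.

    The default floor is 1% of the volume's 99th-percentile THb.
    """
    thb = maps.thb
    if thb_floor is None:
        thb_floor = 0.01 * float(np.percentile(thb, 99))
    out = np.full(thb.shape, np.nan)
    ok = thb >= max(thb_floor, np.finfo(float).tiny)
    out[ok] = maps.hbo2[ok] / thb[ok]
    return out
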