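"""2-D vessel enhancement: MIP, Jerman vesselness, Hessian orientation and
suppression of near-vertical ridge artifacts.

Conventions: 2-D en-face maps are indexed (X, Y); "vertical" means the Y
axis.  Orientation angles are measured from the image-vertical axis and lie
in (-pi/2, pi/2], so a vertical structure has angle ~0 and a horizontal one
~+/-pi/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Volume3D

__all__ = [
    "VesselMap",
    "mip_2d",
    "normalize01",
    "jerman_vesselness",
    "frangi_direction",
    "suppress_vertical",
    "enhance_vessels",
]


@dataclass
class VesselMap:
    """MIP, enhanced ([0,1]), orientation and vertically-suppressed maps."""

    mip: np.ndarray
    enhanced: np.ndarray
    direction: np.ndarray
    suppressed: np.ndarray

    def __post_init__(self) -> None:
        for name in ("enhanced", "suppressed"):
            arr = getattr(self, name)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} map must lie in [0, 1]")
        if (self.suppressed > self.enhanced + 1e-12).any():
            raise ValueError("suppressed map must be <= enhanced map pixelwise")


def mip_2d(volume: Volume3D, mask3d: np.ndarray) -> np.ndarray:
    """Maximum intensity projection along Z over the masked voxels.

    Lateral positions whose masked column is empty project to 0.
    """
    if not mask3d.any():
        raise ValueError("mask is empty; nothing to project")
    masked = np.where(mask3d, volume.values, -np.inf)
    out = masked.max(axis=2)
    return np.where(np.isfinite(out), out, 0.0)


def normalize01(map2d: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; constant maps become all-zero with a warning."""
    lo, hi = float(map2d.min()), float(map2d.max())
    if hi == lo:
        warnings.warn("constant map has no range; returning zeros", stacklevel=2)
        return np.zeros_like(map2d, dtype=np.float64)
    return (map2d - lo) / (hi - lo)


def _hessian2d(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Gaussian Hessian (reflective boundaries).

    The mean is subtracted first: scipy's truncated derivative kernels do
    not sum exactly to zero, so a constant offset would otherwise leave a
    small spurious curvature everywhere.
    """
    img = np.asarray(img, dtype=np.float64)
    img = img - img.mean()
    hxx = gaussian_filter(img, sigma, order=(2, 0), mode="reflect") * sigma**2
    hxy = gaussian_filter(img, sigma, order=(1, 1), mode="reflect") * sigma**2
    hyy = gaussian_filter(img, sigma, order=(0, 2), mode="reflect") * sigma**2
    return hxx, hxy, hyy


def _hessian_eigenvalues(
    hxx: np.ndarray, hxy: np.ndarray, hyy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues ordered by magnitude, |lam1| <= |lam2|."""
    tr_half = (hxx + hyy) / 2
    disc = np.sqrt(((hxx - hyy) / 2) ** 2 + hxy**2)
    e1, e2 = tr_half + disc, tr_half - disc
    swap = np.abs(e1) > np.abs(e2)
    lam1 = np.where(swap, e2, e1)
    lam2 = np.where(swap, e1, e2)
    return lam1, lam2


def jerman_vesselness(map2d: np.ndarray, scale_vox: float = 4.0, tau: float = 0.5) -> np.ndarray:
    """Single-scale 2-D Jerman vesselness, bright-on-dark, rescaled to [0, 1].

    The Hessian is computed at Gaussian scale ``scale_vox``; the response
    uses the regularized eigenvalue ``lam_rho`` with cut-off fraction ``tau``
    of the frame maximum:

    - 0 where ``lam2 <= 0`` or ``lam_rho <= 0``,
    - 1 where ``lam2 >= lam_rho / 2 > 0``,
    - ``lam2^2 (lam_rho - lam2) (3 / (lam2 + lam_rho))^3`` otherwise.
    """
    if not scale_vox > 0:
        raise ValueError("scale must be > 0")
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    hxx, hxy, hyy = _hessian2d(map2d, scale_vox)
    _, lam2 = _hessian_eigenvalues(hxx, hxy, hyy)
    lam = -lam2  # bright vessels on dark background: lam2 < 0
    lam[lam < 0] = 0.0
    mx = float(lam.max())
    # guard against pure roundoff curvature on (near-)uniform frames
    if mx <= 1e-10 * max(1.0, float(np.abs(map2d).max())):
        return np.zeros_like(lam)
    lam_rho = np.where(lam > tau * mx, lam, tau * mx)
    lam_rho[lam <= 0] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        resp = lam**2 * (lam_rho - lam) * (3.0 / (lam + lam_rho)) ** 3
    resp = np.where((lam >= lam_rho / 2) & (lam_rho > 0), 1.0, resp)
    resp[(lam <= 0) | (lam_rho <= 0)] = 0.0
    hi = resp.max()
    return resp / hi if hi > 0 else resp


def frangi_direction(map2d: np.ndarray, scale_vox: float = 4.0) -> np.ndarray:
    """Local vessel-axis orientation from the Hessian eigenvectors.

    The along-vessel axis is the eigenvector of the smaller-magnitude
    eigenvalue (as used by the Frangi filter for direction).  Angles are
    measured from the image-vertical (Y) axis, in (-pi/2, pi/2].
    """
    if not scale_vox > 0:
        raise ValueError("scale must be > 0")
    hxx, hxy, hyy = _hessian2d(map2d, scale_vox)
    tr_half = (hxx + hyy) / 2
    disc = np.sqrt(((hxx - hyy) / 2) ** 2 + hxy**2)
    lam_plus, lam_minus = tr_half + disc, tr_half - disc
    # angle (from the X axis) of the eigenvector of the algebraically larger
    # eigenvalue; the orthogonal direction belongs to the other one
    phi = 0.5 * np.arctan2(2 * hxy, hxx - hyy)
    along = np.where(np.abs(lam_plus) <= np.abs(lam_minus), phi, phi + np.pi / 2)
    theta = np.arctan2(np.cos(along), np.sin(along))  # measured from vertical
    theta = np.where(theta > np.pi / 2, theta - np.pi, theta)
    theta = np.where(theta <= -np.pi / 2, theta + np.pi, theta)
    return theta


def suppress_vertical(
    enhanced: np.ndarray,
    direction: np.ndarray,
    band: tuple[float, float] = (-0.5, 0.5),
) -> np.ndarray:
    """Zero pixels whose orientation lies strictly inside the vertical band."""
    lo, hi = band
    if lo > hi:
        raise ValueError(f"inverted angle band: {band}")
    if enhanced.shape != direction.shape:
        raise ValueError("enhanced and direction maps must share a shape")
    inside = (direction > lo) & (direction < hi)
    return np.where(inside, 0.0, enhanced)


def enhance_vessels(
    pa_volume: Volume3D,
    mask3d: np.ndarray,
    scale_vox: float = 4.0,
    tau: float = 0.5,
    band: tuple[float, float] = (-0.5, 0.5),
) -> VesselMap:
    """MIP -> [0,1] normalization -> Jerman -> orientation -> suppression."""
    mip = mip_2d(pa_volume, mask3d)
    norm = normalize01(mip)
    enhanced = jerman_vesselness(norm, scale_vox=scale_vox, tau=tau)
    direction = frangi_direction(norm, scale_vox=scale_vox)
    suppressed = suppress_vertical(enhanced, direction, band=band)
    return VesselMap(mip=mip, enhanced=enhanced, direction=direction, suppressed=suppressed)
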