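"""Shared image utilities: ROI extraction and spatial smoothing."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import InvalidConfigError, NeurofluidError, TimeSeries

__all__ = ["extract_roi_series", "gaussian_smooth", "FWHM_TO_SIGMA"]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.3548200450309493


def extract_roi_series(volume4d: np.ndarray, mask: np.ndarray, dt: float) -> TimeSeries:
    """Per-frame mean over the mask voxels."""
    vol = np.asarray(volume4d, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if vol.ndim != 4 or m.shape != vol.shape[:3]:
        raise InvalidConfigError("need a 4-D volume and a matching 3-D mask")
    if not m.any():
        raise NeurofluidError("empty ROI mask")
    return TimeSeries(vol[m].mean(axis=0), dt=dt)


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Separable spatial Gaussian smoothing, frame-wise for 4-D input.

    ``sigma = fwhm / 2.3548`` per axis, expressed in voxels via the
    voxel size.  Reflective boundary handling; fwhm = 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise InvalidConfigError("fwhm must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / vs for vs in voxel_size]
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")
    if vol.ndim == 4:
        out = np.empty_like(vol)
        for f in range(vol.shape[-1]):
            out[..., f] = ndimage.gaussian_filter(
                vol[..., f], sigma=sigma_vox, mode="reflect"
            )
        return out
    raise InvalidConfigError("volume must be 3-D or 4-D")
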