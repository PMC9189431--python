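"""Noise suppression, background removal and global thresholding.

All physical parameters are in micrometres and converted to (generally
anisotropic) voxel units internally, so a 4 μm structuring element is a
flat ellipsoid on a 0.2 x 0.2 x 1.0 μm grid rather than a ball of voxels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import (
    threshold_isodata,
    threshold_li,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
    threshold_yen,
)

from embryoseg.io_config import CalibratedVolume, ConfigError

logger = logging.getLogger("embryoseg")

__all__ = ["gaussian_smooth", "tophat_background", "threshold_volume", "THRESHOLD_METHODS"]


def _sigma_voxels(sigmas_um, spacing) -> tuple[float, ...]:
    return tuple(float(s) / float(d) for s, d in zip(sigmas_um, spacing))


def gaussian_smooth(channel: CalibratedVolume, sigmas_um) -> CalibratedVolume:
    """Gaussian-filter a channel with per-axis physical sigmas.

    Parameters
    ----------
    channel : CalibratedVolume
    sigmas_um : float or 3-sequence of float
        Standard deviation of the kernel per (z, y, x) axis in μm; a scalar
        applies isotropically in physical space.  Zero is the identity.

    Uses reflective boundaries, so the global mean is preserved up to
    floating-point error.
    """
    sigmas_um = np.broadcast_to(np.asarray(sigmas_um, dtype=float), (3,))
    if (sigmas_um < 0).any():
        raise ValueError(f"sigmas must be >= 0, got {tuple(sigmas_um)}")
    if (sigmas_um == 0).all():
        return channel.with_data(channel.data.copy())
    sig_vox = _sigma_voxels(sigmas_um, channel.spacing)
    out = ndimage.gaussian_filter(
        channel.data.astype(np.float32, copy=False), sigma=sig_vox, mode="reflect"
    )
    return channel.with_data(out)


def _ellipsoid_footprint(radius_um: float, spacing) -> np.ndarray:
    """Flat ellipsoidal structuring element of the given physical radius."""
    half = [max(1, int(round(radius_um / d))) for d in spacing]
    zz, yy, xx = np.ogrid[-half[0]:half[0] + 1, -half[1]:half[1] + 1, -half[2]:half[2] + 1]
    r2 = (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    ) / radius_um**2
    return r2 <= 1.0


def tophat_background(
    channel: CalibratedVolume, radius_um: float, downsize: int = 1
) -> CalibratedVolume:
    """White top-hat filtering: input minus its grayscale opening.

    Removes background structures larger than an ellipsoidal structuring
    element of physical radius ``radius_um`` while preserving compact bright
    objects (nuclei) smaller than it.  With ``downsize > 1`` the volume is
    block-averaged laterally by that factor before filtering and linearly
    resampled back to the original shape afterwards, trading a small
    approximation error for a large speed-up on big stacks.
    """
    if not radius_um > 0:
        raise ValueError("tophat radius must be > 0")
    downsize = int(downsize)
    if downsize < 1:
        raise ValueError("downsize factor must be >= 1")

    data = channel.data.astype(np.float32, copy=False)
    spacing = np.asarray(channel.spacing, dtype=float)

    if downsize > 1:
        # lateral-only block averaging; z is usually already coarse
        nz, ny, nx = data.shape
        cy, cx = ny // downsize * downsize, nx // downsize * downsize
        small = data[:, :cy, :cx].reshape(nz, cy // downsize, downsize, cx // downsize, downsize)
        small = small.mean(axis=(2, 4))
        small_spacing = (spacing[0], spacing[1] * downsize, spacing[2] * downsize)
    else:
        small = data
        small_spacing = tuple(spacing)

    footprint = _ellipsoid_footprint(radius_um, small_spacing)
    opened = ndimage.grey_opening(small, footprint=footprint, mode="reflect")
    tophat = small - opened

    if downsize > 1:
        zoom = (1.0, data.shape[1] / tophat.shape[1], data.shape[2] / tophat.shape[2])
        tophat = ndimage.zoom(tophat, zoom, order=1, mode="nearest", grid_mode=True)
    out = np.maximum(tophat, 0.0)
    return channel.with_data(out)


THRESHOLD_METHODS = {
    "otsu": threshold_otsu,
    "triangle": threshold_triangle,
    "isodata": threshold_isodata,
    "mean": threshold_mean,
    "li": threshold_li,
    "yen": threshold_yen,
}


def threshold_volume(channel: CalibratedVolume, method: str = "otsu") -> np.ndarray:
    """Threshold a volume with a global histogram method; return a boolean mask.

    The threshold is computed from the full 3D intensity histogram (so it is
    invariant to voxel order) and the mask is ``intensity > threshold``.

    Raises
    ------
    ConfigError
        If ``method`` is not registered.
    """
    try:
        fn = THRESHOLD_METHODS[method]
    except KeyError:
        raise ConfigError(
            f"unknown threshold method {method!r}; available: {sorted(THRESHOLD_METHODS)}"
        ) from None
    data = channel.data
    if np.ptp(data) == 0:
        logger.warning("threshold_volume: constant image, returning empty mask")
        return np.zeros(data.shape, dtype=bool)
    thr = float(fn(data))
    logger.debug("threshold_volume: method=%s threshold=%g", method, thr)
    return data > thr
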