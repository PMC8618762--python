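"""Calibration from the fully sampled k-space center and the b=0 data.

Phase maps are estimated per (gradient, coil) by inverse-transforming a
zero-padded, lightly apodized copy of the fully sampled central band of
lines; the elementwise phase of the resulting low-resolution image is the
diagonal of H(q,c).  Coil sensitivities come from the standard
sum-of-squares combination of the b=0 coil images.  The s0 volume itself is
the per-voxel least-squares combination of the phase-corrected multi-coil
b=0 images.
"""

from __future__ import annotations

import warnings

import numpy as np

from .forward_model import ifft3
from .phantom import CoilProfiles
from .sampling import PHASE_AXIS, SamplingMask

__all__ = ["estimate_phase", "estimate_sensitivities", "recover_s0"]


def estimate_phase(
    samples: np.ndarray,
    mask: SamplingMask,
    grid_shape: tuple,
    apodize: bool = True,
) -> np.ndarray:
    """Unit-modulus phase volume from the central k-space band.

    ``samples`` are the retained samples of one (gradient, coil) in the
    mask's ordering.  The central band is extracted, zero-padded to the full
    grid (centered-DC convention), optionally apodized with a raised cosine
    over its outermost two lines to suppress ringing, inverse-transformed,
    and reduced to its elementwise phase.
    """
    center = np.asarray(mask.center_lines)
    if center.size == 0:
        raise ValueError("mask has no fully sampled central band")
    grid_shape = tuple(grid_shape)
    kfull = np.zeros(grid_shape, dtype=complex)
    kfull[mask.as_array()] = samples
    kcentre = np.zeros_like(kfull)
    kcentre[center] = kfull[center]
    if apodize and 4 < center.size < grid_shape[PHASE_AXIS]:
        # Raised-cosine taper over the outermost 2 lines at each band edge.
        taper = np.ones(center.size)
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(2) + 1) / 3.0))
        taper[:2] = ramp
        taper[-2:] = ramp[::-1]
        shape = [1, 1, 1]
        shape[PHASE_AXIS] = center.size
        kcentre[center] *= taper.reshape(shape)
    img = ifft3(kcentre)
    mag = np.abs(img)
    out = np.ones(grid_shape, dtype=complex)
    nz = mag > 0
    out[nz] = img[nz] / mag[nz]
    return out


def estimate_sensitivities(
    coil_images: np.ndarray, mask: np.ndarray | None = None
) -> CoilProfiles:
    """Sum-of-squares coil sensitivities from C complex b=0 images.

    baseline = sqrt(sum_c |I_c|^2); U_c = I_c / baseline, so that
    sum_c |U_c|^2 = 1 wherever the baseline is nonzero.  Voxels with a zero
    baseline inside the requested mask are zeroed with a warning.
    """
    imgs = np.asarray(coil_images)
    if imgs.ndim != 4 or imgs.shape[0] < 1:
        raise ValueError("coil_images must have shape (C, *grid)")
    baseline = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    nz = baseline > 0
    if mask is not None and (~nz & mask).any():
        warnings.warn("zero-baseline voxels inside the mask were zeroed")
    U = np.zeros_like(imgs)
    U[:, nz] = imgs[:, nz] / baseline[nz]
    return CoilProfiles(maps=U)


def recover_s0(
    kdata_b0: np.ndarray,
    coils: CoilProfiles,
    phases_b0: np.ndarray,
) -> np.ndarray:
    """Least-squares s0 from fully sampled multi-coil b=0 k-space.

    Per voxel the model is img_c = U_c H_c s0 with real s0 >= unknown; the
    weighted least-squares solution is

        s0 = Re( sum_c conj(U_c H_c) img_c ) / sum_c |U_c|^2

    (|H_c| = 1).  Degenerate voxels (zero denominator) are left at zero.
    """
    kdata_b0 = np.asarray(kdata_b0)
    C = coils.C
    if kdata_b0.shape[0] != C or phases_b0.shape[0] != C:
        raise ValueError("kdata_b0 and phases_b0 must be indexed per coil")
    imgs = ifft3(kdata_b0.reshape((C,) + coils.maps.shape[1:]))
    num = np.sum(np.real(np.conj(coils.maps * phases_b0) * imgs), axis=0)
    den = np.sum(np.abs(coils.maps) ** 2, axis=0)
    out = np.zeros_like(den)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out
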