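"""Voxelized phantoms: 4D dynamic PET grids and multi-b DWI stacks.

These exist so the segmentation -> TAC extraction -> kinetic fitting chain
and the ADC chain can be exercised end to end with known ground truth.  No
scanner physics (resolution, scatter, attenuation) is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GA68_HALF_LIFE_MIN, FrameSchedule, TimeActivityCurve
from .simulate import tac_noise_sd


@dataclass(frozen=True)
class PhantomGeometry:
    """Spherical lesion plus a rectangular reference slab inside a 3D grid.

    All lengths in mm; ``shape`` in voxels, axis order (x, y, z).
    The reference slab spans ``ref_slab_x`` (voxel index range along x) over
    the full y/z extent.
    """

    shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_center_mm: tuple[float, float, float] = (30.0, 30.0, 20.0)
    lesion_radius_mm: float = 8.0
    ref_slab_x: tuple[int, int] = (0, 6)


def _voxel_centers(shape, voxel_size_mm):
    axes = [(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size_mm)]
    return np.meshgrid(*axes, indexing="ij")


def make_masks(geometry: PhantomGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (lesion, reference) masks; raises if they overlap or the lesion leaves the grid."""
    gx, gy, gz = _voxel_centers(geometry.shape, geometry.voxel_size_mm)
    cx, cy, cz = geometry.lesion_center_mm
    r2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    lesion = r2 <= geometry.lesion_radius_mm**2
    extent = [n * v for n, v in zip(geometry.shape, geometry.voxel_size_mm)]
    for c, e in zip(geometry.lesion_center_mm, extent):
        if c - geometry.lesion_radius_mm < 0 or c + geometry.lesion_radius_mm > e:
            raise ValueError("lesion sphere does not fit inside the grid")
    ref = np.zeros(geometry.shape, dtype=bool)
    ref[geometry.ref_slab_x[0] : geometry.ref_slab_x[1], :, :] = True
    if np.any(lesion & ref):
        raise ValueError("lesion and reference regions overlap")
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    return lesion, ref


def generate_dynamic_phantom(
    lesion_tac: TimeActivityCurve,
    reference_tac: TimeActivityCurve,
    schedule: FrameSchedule,
    geometry: PhantomGeometry | None = None,
    background_level: float = 0.0,
    noise_scale: float = 0.0,
    half_life_min: float = GA68_HALF_LIFE_MIN,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a 4D (x, y, z, frame) dynamic image with known truth masks.

    Lesion-sphere voxels carry the lesion TAC, the reference slab the
    reference TAC, everything else a flat background.  Optional per-voxel
    Gaussian noise follows the frame-statistics variance law.

    Returns (image, lesion_mask, reference_mask).
    """
    geometry = geometry or PhantomGeometry()
    if lesion_tac.n_frames != schedule.n_frames or reference_tac.n_frames != schedule.n_frames:
        raise ValueError("TAC length must match the frame schedule")
    lesion, ref = make_masks(geometry)
    img = np.full((*geometry.shape, schedule.n_frames), float(background_level))
    img[lesion, :] = lesion_tac.conc
    img[ref, :] = reference_tac.conc
    if noise_scale > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sd = tac_noise_sd(img, schedule.mid_times_min, schedule.durations_min,
                          noise_scale, half_life_min)
        img = img + rng.standard_normal(img.shape) * sd
    return img, lesion, ref


def generate_dwi_series(
    s0_map: np.ndarray,
    adc_map: np.ndarray,
    b_values: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Mono-exponential diffusion signal S(b) = S0 exp(-b * ADC) plus Gaussian noise.

    ``adc_map`` in mm^2/s, ``b_values`` in s/mm^2.  Output axis order is
    (..., b).  Gaussian (not Rician) noise: adequate at the high lesion SNR
    simulated here, where magnitude bias is negligible.
    """
    s0 = np.asarray(s0_map, dtype=float)
    adc = np.asarray(adc_map, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or b.size < 1:
        raise ValueError("b_values must be a 1-D array")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if np.any((s0 > 0) & (adc < 0)):
        raise ValueError("ADC must be non-negative where signal is present")
    sig = s0[..., None] * np.exp(-b * adc[..., None])
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sig = sig + rng.standard_normal(sig.shape) * noise_sd
    return sig
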