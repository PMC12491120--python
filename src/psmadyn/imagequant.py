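"""PET image quantification: decay correction, lesion VOI segmentation,
TAC extraction and SUV / SUVpeak measurement.

Coordinate conventions: 0-based voxel indices, axis order (x, y, z[, frame]);
world coordinates are mm from the grid origin with voxel centres at
(index + 0.5) * voxel_size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GA68_HALF_LIFE_MIN, FrameSchedule, TimeActivityCurve
from .srtm import compute_fit_weights

# radius of a 1 ml sphere, mm: (3 * 1000 mm^3 / 4 pi)^(1/3)
ONE_ML_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # faces only


@dataclass(frozen=True)
class Injection:
    """Tracer administration metadata."""

    dose_Bq: float
    weight_g: float
    half_life_min: float = GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.dose_Bq <= 0 or self.weight_g <= 0:
            raise ValueError("dose and weight must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")


@dataclass
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) in Bq/ml."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    injection: Injection
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis length must match the schedule")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class VOIMask:
    """Boolean 3D mask plus provenance of how it was drawn."""

    mask: np.ndarray
    method: str = "manual"
    threshold: float | None = None
    search_region: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def decay_correction_factors(schedule: FrameSchedule, half_life_min: float) -> np.ndarray:
    """Per-frame factor referring activity back to injection time.

    For a frame [t0, t0+dt] the measured mean activity is the decayed
    time-average; the exact correction is e^{lambda t0} * lambda dt /
    (1 - e^{-lambda dt}) with lambda = ln 2 / half-life.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    lam = np.log(2.0) / (half_life_min * 60.0)  # /s, schedule is in seconds
    t0 = schedule.start_times
    dt = schedule.durations
    # -expm1 keeps the short-frame limit (factor -> 1) accurate
    return np.exp(lam * t0) * (lam * dt) / (-np.expm1(-lam * dt))


def decay_correct(obj, half_life_min: float | None = None):
    """Decay-correct a DynamicImage or TimeActivityCurve to injection time.

    Refuses to correct twice (DynamicImage tracks a flag).  For a bare TAC
    the half-life must be supplied.
    """
    if isinstance(obj, DynamicImage):
        if obj.decay_corrected:
            raise ValueError("image is already decay corrected")
        f = decay_correction_factors(obj.schedule, obj.injection.half_life_min)
        return DynamicImage(obj.voxels * f, obj.voxel_size_mm, obj.schedule,
                            obj.injection, decay_corrected=True)
    if isinstance(obj, TimeActivityCurve):
        if half_life_min is None:
            raise ValueError("half-life required to correct a TAC")
        if half_life_min <= 0:
            raise ValueError("half-life must be positive")
        lam = np.log(2.0) / half_life_min
        t0 = obj.t_min - 0.5 * obj.dt_min
        f = np.exp(lam * t0) * (lam * obj.dt_min) / (-np.expm1(-lam * obj.dt_min))
        return obj.copy_with(conc=obj.conc * f)
    raise TypeError("expected DynamicImage or TimeActivityCurve")


def _sphere_voxels(shape, voxel_size_mm, center_vox, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within radius_mm of a voxel centre."""
    idx = [np.arange(n) for n in shape]
    gx, gy, gz = np.meshgrid(*idx, indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip((gx, gy, gz), center_vox, voxel_size_mm))
    return d2 <= radius_mm**2


def segment_lesion_40pct(
    static_frame: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    seed_voxel: tuple[int, int, int],
    search_radius_mm: float,
    threshold_fraction: float = 0.40,
) -> VOIMask:
    """Adaptive relative-threshold lesion delineation.

    Threshold = ``threshold_fraction`` x the maximum voxel value inside the
    search sphere around the seed; the mask is the 6-connected component of
    supra-threshold voxels (within the sphere) that contains that maximum.
    """
    img = np.asarray(static_frame, dtype=float)
    if img.ndim != 3:
        raise ValueError("static frame must be 3-D")
    if not all(0 <= s < n for s, n in zip(seed_voxel, img.shape)):
        raise ValueError("seed voxel outside the image grid")
    sphere = _sphere_voxels(img.shape, voxel_size_mm, seed_voxel, search_radius_mm)
    if not sphere.any():
        raise ValueError("search sphere is empty")
    region = np.where(sphere, img, -np.inf)
    peak = np.unravel_index(np.argmax(region), img.shape)
    peak_val = img[peak]
    if peak_val <= 0:
        raise ValueError("no signal in the search region")
    thr = threshold_fraction * peak_val
    supra = (img >= thr) & sphere
    labels, _ = ndimage.label(supra, structure=_STRUCT_6)
    comp = labels == labels[peak]
    return VOIMask(comp, method=f"adaptive{int(round(100 * threshold_fraction))}",
                   threshold=float(thr),
                   search_region=f"sphere r={search_radius_mm}mm @ {tuple(seed_voxel)}")


def extract_tac(dynamic: DynamicImage, voi: VOIMask,
                weight_half_life_min: float | None = None) -> TimeActivityCurve:
    """Frame-wise unweighted mean over the VOI, with kinetic fitting weights attached."""
    if voi.mask.shape != dynamic.voxels.shape[:3]:
        raise ValueError("mask does not match the image grid")
    conc = dynamic.voxels[voi.mask, :].mean(axis=0)
    tac = TimeActivityCurve.from_schedule(dynamic.schedule, conc)
    hl = weight_half_life_min if weight_half_life_min is not None else dynamic.injection.half_life_min
    tac.weights = compute_fit_weights(tac, hl)
    return tac


def suv_convert(concentration_Bq_ml, injection: Injection) -> np.ndarray | float:
    """Standardized uptake value: concentration / (dose / body weight), 1 g/ml tissue."""
    return np.asarray(concentration_Bq_ml, dtype=float) / (injection.dose_Bq / injection.weight_g)


def suv_peak(
    static_frame: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    voi: VOIMask,
    injection: Injection,
    sphere_radius_mm: float = ONE_ML_SPHERE_RADIUS_MM,
    centers: str = "mask",
) -> float:
    """Maximum mean SUV over 1-ml spheres centred on lesion voxels.

    Sphere membership is by voxel-centre inclusion; candidate centres are the
    VOI voxels (``centers='mask'``) so the peak stays a sub-volume of the
    lesion, or every voxel (``centers='all'``).
    """
    img = np.asarray(static_frame, dtype=float)
    if voi.mask.shape != img.shape:
        raise ValueError("mask does not match the image grid")
    suv = suv_convert(img, injection)
    # sphere offsets in voxel units
    rad_vox = [int(np.floor(sphere_radius_mm / v)) for v in voxel_size_mm]
    offs = np.meshgrid(*[np.arange(-r, r + 1) for r in rad_vox], indexing="ij")
    d2 = sum((o * v) ** 2 for o, v in zip(offs, voxel_size_mm))
    inside = d2 <= sphere_radius_mm**2
    offsets = np.stack([o[inside] for o in offs], axis=1)
    cand = np.argwhere(voi.mask) if centers == "mask" else np.argwhere(np.ones_like(img, bool))
    best = -np.inf
    shape = np.array(img.shape)
    for c in cand:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        p = pts[ok]
        m = suv[p[:, 0], p[:, 1], p[:, 2]].mean()
        if m > best:
            best = m
    return float(best)
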