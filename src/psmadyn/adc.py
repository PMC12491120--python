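"""Apparent diffusion coefficient (ADC) estimation from multi-b DWI.

Mono-exponential signal model S(b) = S0 exp(-b * ADC), fitted per voxel by
weighted log-linear least squares with weights proportional to S^2.  At high
SNR this matches the full nonlinear fit while staying deterministic (no
starting values), which is why scanner consoles commonly use it.
ADC is reported in mm^2/s (display convention x10^-3 mm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ADCResult:
    """Per-voxel mono-exponential fit over a region."""

    s0_map: np.ndarray
    adc_map: np.ndarray  # mm^2/s; NaN where excluded
    lesion_mean_adc: float | None
    n_voxels_used: int
    n_voxels_excluded: int


def fit_adc_monoexp(signals: np.ndarray, b_values: np.ndarray) -> ADCResult:
    """Fit S(b) = S0 exp(-b ADC) voxel-wise.

    ``signals`` has shape (..., n_b) matching ``b_values``.  Voxels with any
    non-positive signal cannot enter the log fit; they are excluded and
    counted.  For two b-values the weighted fit reduces exactly to the
    closed-form two-point estimator ln(S(b1)/S(b2)) / (b2 - b1).
    """
    sig = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if sig.shape[-1] != b.size:
        raise ValueError("last signal axis must match b_values")

    flat = sig.reshape(-1, b.size)
    ok = np.all(flat > 0, axis=1)
    n_exc = int((~ok).sum())
    if not ok.any():
        raise ValueError("all voxels excluded (non-positive signals)")

    s = flat[ok]
    ln_s = np.log(s)
    w = s**2
    # weighted straight-line fit of ln S on b, vectorized over voxels
    sw = w.sum(axis=1)
    bm = (w * b).sum(axis=1) / sw
    ym = (w * ln_s).sum(axis=1) / sw
    cov = (w * (b - bm[:, None]) * (ln_s - ym[:, None])).sum(axis=1)
    var = (w * (b - bm[:, None]) ** 2).sum(axis=1)
    slope = cov / var
    adc = -slope
    s0 = np.exp(ym - slope * bm)

    adc_map = np.full(flat.shape[0], np.nan)
    s0_map = np.full(flat.shape[0], np.nan)
    adc_map[ok] = adc
    s0_map[ok] = s0
    shape = sig.shape[:-1]
    adc_map = adc_map.reshape(shape)
    s0_map = s0_map.reshape(shape)
    mean = float(np.nanmean(adc_map)) if np.isfinite(adc_map).any() else None
    return ADCResult(s0_map, adc_map, mean, int(ok.sum()), n_exc)


def lesion_mean_adc(adc_map: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean ADC over included (finite) mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(adc_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no usable voxels in the mask")
    return float(vals.mean())
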