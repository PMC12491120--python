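"""File I/O contracts: NIfTI volumes with JSON sidecars, TAC CSVs, bvals.

Axis order inside arrays is (x, y, z[, frame]); NIfTI affines are diagonal
with the voxel size in mm (no orientation handling — phantom data).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FrameSchedule, TimeActivityCurve

TAC_COLUMNS = ["t_mid_min", "dt_min", "conc_Bq_ml", "weight"]


def save_nifti(path, array: np.ndarray, voxel_size_mm) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()), tuple(float(z) for z in zooms)


def save_mask(path, mask: np.ndarray, voxel_size_mm) -> None:
    save_nifti(path, mask.astype(np.uint8), voxel_size_mm)


def save_sidecar(path, schedule: FrameSchedule, *, injected_dose_MBq: float,
                 weight_kg: float, half_life_min: float, seed=None) -> None:
    payload = {
        "frame_starts_s": schedule.start_times.tolist(),
        "frame_durations_s": schedule.durations.tolist(),
        "injected_dose_MBq": injected_dose_MBq,
        "weight_kg": weight_kg,
        "half_life_min": half_life_min,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_sidecar(path) -> dict:
    meta = json.loads(Path(path).read_text())
    meta["schedule"] = FrameSchedule(np.asarray(meta["frame_starts_s"]),
                                     np.asarray(meta["frame_durations_s"]))
    return meta


def save_tac(path, tac: TimeActivityCurve) -> None:
    w = tac.weights if tac.weights is not None else np.ones(tac.n_frames)
    pd.DataFrame(dict(zip(TAC_COLUMNS, [tac.t_min, tac.dt_min, tac.conc, w]))).to_csv(
        path, index=False)


def load_tac(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file lacks columns {missing}")
    w = df["weight"].to_numpy() if "weight" in df.columns else None
    return TimeActivityCurve(df["t_mid_min"].to_numpy(), df["dt_min"].to_numpy(),
                             df["conc_Bq_ml"].to_numpy(), w)


def load_bvals(path) -> np.ndarray:
    """FSL-style bval file: whitespace-separated values on one line."""
    return np.loadtxt(str(path), ndmin=1)
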