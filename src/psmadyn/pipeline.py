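"""End-to-end study pipeline: simulate -> quantify -> fit -> analyze -> report.

Each stage writes its artifacts under a run directory and every output is
stamped with the global seed and a hash of the configuration, so a run is
reproducible from its provenance file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import fit_adc_monoexp, lesion_mean_adc
from .cohort import CohortSimConfig, generate_cohort
from .core import GA68_HALF_LIFE_MIN, FrameSchedule
from .imagequant import (DynamicImage, Injection, VOIMask, extract_tac,
                         segment_lesion_40pct, suv_peak)
from .phantom import PhantomGeometry, generate_dwi_series, generate_dynamic_phantom
from .simulate import (KineticGroundTruth, add_tac_noise, make_input_function,
                       reference_fine_curve, simulate_lesion_tac_srtm,
                       simulate_reference_tac)
from .srtm import fit_srtm
from .stats import (agreement_lme, compute_fold_changes, concordance_correlation,
                    fit_lme, pivot_changes, summarize_trajectories)

PET_NEGATIVE_PATIENTS = ("P2",)


def load_psa_fixture() -> pd.DataFrame:
    """The packaged 8-patient serum-PSA series (ng/mL) at days 0/7/21/28.

    Missing visits are explicit NaN; ``pet_negative`` marks the patient who
    showed no tracer-avid lesion and is excluded from imaging analyses.
    Returned in the long visit-table layout (metric = "PSA").
    """
    ref = importlib.resources.files("psmadyn.data").joinpath("psa_table1.csv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df["pet_negative"] = df["pet_negative"].astype(bool)
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "lesion_id": pd.NA,
        "day": df["day"].astype(int),
        "metric": "PSA",
        "value": df["psa_ng_ml"],
        "pet_negative": df["pet_negative"],
    })
    return out


@dataclass
class StudyConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    visit_days: tuple[int, ...] = (0, 7, 21, 28)
    n_patients: int = 8
    exclude_patients: tuple[str, ...] = ()
    half_life_min: float = GA68_HALF_LIFE_MIN
    b_values: tuple[float, ...] = (0.0, 800.0)
    simulate_imaging: bool = True
    tac_noise_scale: float = 0.0
    cohort_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if 0 not in self.visit_days:
            raise ValueError("visit_days must include baseline day 0")
        if len(self.b_values) < 2:
            raise ValueError("need at least two b-values")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients for mixed models")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return json.loads(x.to_json(orient="index"))
    raise TypeError(type(x))


def run_pipeline(config: StudyConfig) -> dict:
    """Execute all stages and return the report bundle (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    timings = {}
    report: dict = {"provenance": stamp}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                res = fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            timings[name] = round(time.perf_counter() - t0, 3)
            return res
        return deco

    # -- stage: simulate cohort ------------------------------------------
    def _simulate():
        cfg = CohortSimConfig(n_patients=config.n_patients,
                              visit_days=tuple(config.visit_days),
                              seed=config.seed, **config.cohort_overrides)
        visits = generate_cohort(cfg)
        visits.insert(0, "config_hash", stamp["config_hash"])
        visits.to_csv(out / "visits.csv", index=False)
        return visits.drop(columns="config_hash")

    visits = stage("simulate_cohort")(_simulate)

    # -- stage: imaging chain on one phantom visit ------------------------
    if config.simulate_imaging:
        def _imaging():
            rng = np.random.default_rng(config.seed + 1)
            schedule = FrameSchedule.dynamic_55frame()
            truth = KineticGroundTruth()
            cp = make_input_function(truth.input_function_params)
            ref_fine = reference_fine_curve(cp, truth.reference_params, schedule)
            ref_tac = simulate_reference_tac(cp, truth.reference_params, schedule)
            les_tac = simulate_lesion_tac_srtm(ref_fine, truth, schedule)
            if config.tac_noise_scale > 0:
                les_tac = add_tac_noise(les_tac, config.tac_noise_scale,
                                        config.half_life_min, rng)
            geom = PhantomGeometry()
            img, lesion_mask, ref_mask = generate_dynamic_phantom(
                les_tac, ref_tac, schedule, geom, background_level=50.0, seed=rng)
            inj = Injection(dose_Bq=160e6, weight_g=80e3, half_life_min=config.half_life_min)
            dyn = DynamicImage(img, geom.voxel_size_mm, schedule, inj, decay_corrected=True)
            late = img[..., -1]
            seed_vox = tuple(int(round(c / v)) for c, v in
                             zip(geom.lesion_center_mm, geom.voxel_size_mm))
            voi = segment_lesion_40pct(late, geom.voxel_size_mm, seed_vox, 20.0)
            tac = extract_tac(dyn, voi)
            ref_voi_tac = extract_tac(dyn, VOIMask(ref_mask, method="manual"))
            fit = fit_srtm(tac, ref_voi_tac)
            peak = suv_peak(late, geom.voxel_size_mm, voi, inj)
            # DWI chain on the same lesion geometry
            s0 = np.where(lesion_mask, 1000.0, 800.0)
            adc_true = np.where(lesion_mask, 0.8e-3, 1.5e-3)
            dwi = generate_dwi_series(s0, adc_true, np.asarray(config.b_values),
                                      noise_sd=0.0, seed=rng)
            adc_res = fit_adc_monoexp(dwi, np.asarray(config.b_values))
            mean_adc = lesion_mean_adc(adc_res.adc_map, lesion_mask)
            return {
                "truth": {"R1": truth.R1, "k2": truth.k2, "bp_nd": truth.bp_nd},
                "srtm_fit": {"R1": fit.R1, "k2": fit.k2, "bp_nd": fit.bp_nd,
                             "converged": fit.converged, "wrss": fit.weighted_rss},
                "segmentation": {"n_voxels": voi.n_voxels,
                                 "n_truth_voxels": int(lesion_mask.sum())},
                "suv_peak": peak,
                "lesion_mean_adc_mm2_s": mean_adc,
                "adc_truth_mm2_s": 0.8e-3,
            }

        report["imaging"] = stage("imaging_chain")(_imaging)

    # -- stage: longitudinal analysis -------------------------------------
    def _analyze():
        traj = compute_fold_changes(visits, exclude_patients=config.exclude_patients)
        traj.to_csv(out / "fold_changes.csv", index=False)
        summary = summarize_trajectories(traj)
        summary.to_csv(out / "group_summary.csv", index=False)
        wide = pivot_changes(traj)
        models = {}
        psa = traj[traj["metric"] == "PSA"].rename(columns={"pct_change": "psa_pct"})
        m_psa = fit_lme(psa, response="psa_pct", fixed_terms=("day",), group="patient_id")
        models["psa_linear"] = m_psa.fixed_effects
        m_bp = fit_lme(wide.dropna(subset=["bpnd_pct"]), response="bpnd_pct",
                       fixed_terms=("day", "day2", "day3"), group="patient_id")
        models["bpnd_cubic"] = m_bp.fixed_effects
        m_adc = fit_lme(wide.dropna(subset=["adc_pct"]), response="adc_pct",
                        fixed_terms=("day",), group="patient_id")
        models["adc_linear"] = m_adc.fixed_effects
        try:
            m_ext = fit_lme(wide.dropna(subset=["bpnd_pct", "adc_pct"]),
                            response="bpnd_pct",
                            fixed_terms=("day", "day2", "day3", "adc_pct"),
                            group="patient_id")
            models["bpnd_extended"] = m_ext.fixed_effects
        except ValueError as e:
            # e.g. a noise-free cohort makes dADC% exactly collinear with day
            models["bpnd_extended"] = {"error": str(e)}
        follow = wide[wide["day"] > 0].dropna(subset=["suv_pct", "bpnd_pct"])
        agr = agreement_lme(follow, "suv_pct", "bpnd_pct", "lesion_id")
        ccc, est = concordance_correlation(follow["suv_pct"], follow["bpnd_pct"])
        payload = {name: fe for name, fe in models.items()}
        payload["agreement"] = {"bias": agr.bias, "loa_low": agr.loa_low,
                                "loa_high": agr.loa_high, "n_pairs": agr.n_pairs,
                                "ccc": ccc, "ccc_estimator": est}
        (out / "models.json").write_text(json.dumps({**stamp, **payload},
                                                    default=_jsonable, indent=2))
        return payload

    report["analysis"] = stage("trajectory_analysis")(_analyze)

    # -- provenance -------------------------------------------------------
    prov = {
        **stamp,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seconds": timings,
    }
    (out / "provenance.json").write_text(json.dumps(prov, default=_jsonable, indent=2))
    report["provenance"] = prov
    return report
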