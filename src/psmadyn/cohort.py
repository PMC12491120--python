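"""Longitudinal cohort simulator.

Emulates the study design this package analyses: patients on short-term
androgen blockade imaged at days 0, 7, 21 and 28, with per-lesion binding
potential (BP_ND), ADC and SUVpeak, and per-patient serum PSA.

Generating model, in fold-change space (percent from baseline):

* dBP_ND%  : cubic polynomial in day  + patient (and optional lesion)
             random intercept + Gaussian residual       (biphasic rebound)
* dADC%    : linear slope in day      + random intercept + residual
* dSUV%    : linear slope in day      + random intercept + residual
* PSA      : baseline * exp(-rate * day) * lognormal noise (kept positive)

Baseline (day 0) records have zero fold change by construction; random
effects and residuals apply to follow-up visits only.  Absolute metric
values are reconstructed from simulated patient baselines.

Default trajectory coefficients are the group-level longitudinal estimates
this kind of study reports (cubic BP_ND% course with coefficients
(-5.63, 1.11, -0.03) per day/day^2/day^3, ADC slope +1.66 %/day, SUV slope
-0.83 %/day, PSA decline rate 0.077 /day, i.e. ~88% drop by day 28).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VISIT_DAYS_DEFAULT = (0, 7, 21, 28)
METRICS = ("BPND", "ADC", "SUVpeak", "PSA")


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the longitudinal cohort generator.

    ``bpnd_poly`` are the (linear, quadratic, cubic) coefficients of the
    mean dBP_ND% trajectory in %/day^k; slopes in %/day; ``psa_decline_rate``
    in /day.  SD entries are per-patient random-intercept SDs
    (``random_effect_sds``), per-lesion intercept SD (``lesion_sd``) and
    residual SDs (``residual_sds``), all in percentage points except the
    lognormal ``residual_sds['PSA']`` (SD of log PSA).
    """

    n_patients: int = 8
    lesions_per_patient: int = 1
    visit_days: tuple[int, ...] = VISIT_DAYS_DEFAULT
    bpnd_poly: tuple[float, float, float] = (-5.63, 1.11, -0.03)
    adc_slope: float = 1.66
    suv_slope: float = -0.83
    psa_decline_rate: float = 0.077
    random_effect_sds: dict = field(
        default_factory=lambda: {"BPND": 15.0, "ADC": 8.0, "SUVpeak": 10.0}
    )
    lesion_sd: float = 0.0
    residual_sds: dict = field(
        default_factory=lambda: {"BPND": 20.0, "ADC": 10.0, "SUVpeak": 12.0, "PSA": 0.10}
    )
    baseline_bpnd_median: float = 2.0
    baseline_adc_median: float = 0.8e-3  # mm^2/s
    baseline_suv_median: float = 8.0
    baseline_psa_median: float = 15.0  # ng/mL
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.lesions_per_patient < 1:
            raise ValueError("lesions_per_patient must be at least 1")
        if 0 not in self.visit_days:
            raise ValueError("visit_days must include the baseline day 0")
        sds = list(self.random_effect_sds.values()) + list(self.residual_sds.values())
        if any(s < 0 for s in sds) or self.lesion_sd < 0:
            raise ValueError("all SDs must be non-negative")


def bpnd_mean_pct(config: CohortSimConfig, day: np.ndarray) -> np.ndarray:
    """Mean dBP_ND% trajectory: b1*d + b2*d^2 + b3*d^3 (zero at baseline)."""
    b1, b2, b3 = config.bpnd_poly
    d = np.asarray(day, dtype=float)
    return b1 * d + b2 * d**2 + b3 * d**3


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate the cohort as a long-format visit table.

    Returns a DataFrame with columns (patient_id, lesion_id, day, metric,
    value); PSA rows are per patient (lesion_id is NA).  Reproducible for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(sorted(config.visit_days), dtype=float)
    follow = days > 0
    rows: list[tuple] = []

    for p in range(1, config.n_patients + 1):
        pid = f"P{p:03d}"
        base_psa = config.baseline_psa_median * rng.lognormal(0.0, 0.9)
        # per-patient random intercepts (fold-change space, follow-up only)
        u = {m: rng.normal(0.0, config.random_effect_sds.get(m, 0.0))
             for m in ("BPND", "ADC", "SUVpeak")}

        psa = base_psa * np.exp(-config.psa_decline_rate * days)
        noise = np.where(follow, rng.normal(0.0, config.residual_sds["PSA"], days.size), 0.0)
        psa = psa * np.exp(noise)
        for d, v in zip(days, psa):
            rows.append((pid, pd.NA, int(d), "PSA", v))

        for li in range(1, config.lesions_per_patient + 1):
            lid = f"{pid}-L{li}"
            v_les = rng.normal(0.0, config.lesion_sd)
            base = {
                "BPND": config.baseline_bpnd_median * rng.lognormal(0.0, 0.3),
                "ADC": config.baseline_adc_median * rng.lognormal(0.0, 0.15),
                "SUVpeak": config.baseline_suv_median * rng.lognormal(0.0, 0.4),
            }
            mean_pct = {
                "BPND": bpnd_mean_pct(config, days),
                "ADC": config.adc_slope * days,
                "SUVpeak": config.suv_slope * days,
            }
            for m in ("BPND", "ADC", "SUVpeak"):
                eps = rng.normal(0.0, config.residual_sds.get(m, 0.0), days.size)
                pct = np.where(follow, mean_pct[m] + u[m] + v_les + eps, 0.0)
                vals = base[m] * (1.0 + pct / 100.0)
                for d, v in zip(days, vals):
                    rows.append((pid, lid, int(d), m, v))

    return pd.DataFrame(rows, columns=["patient_id", "lesion_id", "day", "metric", "value"])
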