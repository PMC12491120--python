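"""Kinetic ground-truth simulators: plasma input, reference and lesion TACs.

The forward chain emulates a dynamic pelvic PET acquisition after bolus
injection of a PSMA-targeting tracer:

1. a tri-exponential (Feng-type) plasma input function drives
2. a one-tissue reference region (receptor-free muscle), which in turn drives
3. the lesion via the simplified reference tissue model (SRTM)

   C_T(t) = R1 * C_R(t) + (k2 - R1*k2a) * (C_R (*) exp(-k2a t)),
   k2a = k2 / (1 + BP_ND)

Continuous kinetics are evaluated on a fine internal grid (default 0.01 min)
and frame values are frame-averaged, matching how PET frames integrate
counts.  Exponential convolutions use the exact piecewise-linear closed form,
so the simulators agree with stiff-ODE and brute-force-convolution oracles to
high precision.

The default rate constants are plausible values for PSMA tracers in pelvic
tissue chosen for simulation purposes; they are not measured study values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GA68_HALF_LIFE_MIN, FrameSchedule, TimeActivityCurve, frame_average

DEFAULT_FINE_DT_MIN = 0.01

__all__ = [
    "FengParams",
    "OneTissueParams",
    "KineticGroundTruth",
    "make_input_function",
    "exp_conv",
    "reference_fine_curve",
    "simulate_reference_tac",
    "simulate_lesion_tac_srtm",
    "add_tac_noise",
    "DEFAULT_FINE_DT_MIN",
]


@dataclass(frozen=True)
class FengParams:
    """Tri-exponential bolus input model.

    C_p(t) = (a1*(t-tau) - a2 - a3) e^{-l1 (t-tau)} + a2 e^{-l2 (t-tau)}
             + a3 e^{-l3 (t-tau)}  for t > tau, else 0.

    Amplitudes in Bq/ml (a1 in Bq/ml/min), eigenvalues in /min, delay tau in
    min.  Defaults are the classic bolus shape parameters scaled to a
    clinically plausible peak of ~25 kBq/ml.
    """

    a1: float = 851.1225 * 40.0
    a2: float = 21.8798 * 40.0
    a3: float = 20.8113 * 40.0
    l1: float = 4.133859
    l2: float = 0.01043449
    l3: float = 0.1190996
    tau: float = 0.5


@dataclass(frozen=True)
class OneTissueParams:
    """One-tissue-compartment parameters: K1 (ml/ccm/min) and k2 (/min)."""

    K1: float = 0.1
    k2: float = 0.12

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError("K1 must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")


@dataclass(frozen=True)
class KineticGroundTruth:
    """True SRTM parameters plus the upstream drivers that generate them."""

    R1: float = 1.2
    k2: float = 0.3
    bp_nd: float = 2.0
    reference_params: OneTissueParams = field(default_factory=OneTissueParams)
    input_function_params: FengParams = field(default_factory=FengParams)

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if 1.0 + self.bp_nd <= 0:
            raise ValueError("BP_ND must exceed -1")

    @property
    def k2a(self) -> float:
        """Apparent efflux rate k2 / (1 + BP_ND), /min."""
        return self.k2 / (1.0 + self.bp_nd)


class InputFunction:
    """Continuous-time evaluable plasma concentration curve (Bq/ml)."""

    def __init__(self, params: FengParams):
        self.params = params
        # reject parameter sets whose curve dips negative anywhere relevant
        t_chk = np.linspace(0.0, 240.0, 24001)
        if np.min(self._eval(t_chk)) < -1e-9:
            raise ValueError("input-function parameters produce negative concentrations")

    def _eval(self, t: np.ndarray) -> np.ndarray:
        p = self.params
        s = np.asarray(t, dtype=float) - p.tau
        out = np.zeros_like(s)
        pos = s > 0
        sp = s[pos]
        out[pos] = (
            (p.a1 * sp - p.a2 - p.a3) * np.exp(-p.l1 * sp)
            + p.a2 * np.exp(-p.l2 * sp)
            + p.a3 * np.exp(-p.l3 * sp)
        )
        return out

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return self._eval(t)


def make_input_function(params: FengParams | None = None) -> InputFunction:
    """Build the plasma input curve; zero at t=0 and non-negative by validation."""
    return InputFunction(params if params is not None else FengParams())


def exp_conv(c: np.ndarray, k: float, dt: float) -> np.ndarray:
    """(c (*) exp(-k t)) on a uniform grid, exact for piecewise-linear c.

    Recursive update y[i+1] = y[i] e^{-k dt} + closed-form integral of the
    linear segment against the exponential kernel.  k = 0 reduces to the
    cumulative trapezoid.
    """
    c = np.asarray(c, dtype=float)
    if k < 0:
        raise ValueError("decay rate k must be non-negative")
    y = np.zeros_like(c)
    kdt = k * dt
    if kdt < 1e-12:
        np.cumsum(0.5 * dt * (c[1:] + c[:-1]), out=y[1:])
        return y
    e = np.exp(-kdt)
    A = (1.0 - e) / k
    B = A - (1.0 - e - kdt * e) / (k * kdt)
    w0, w1 = A - B, B
    for i in range(c.size - 1):
        y[i + 1] = y[i] * e + w0 * c[i] + w1 * c[i + 1]
    return y


def _fine_grid(schedule: FrameSchedule, dt_min: float) -> np.ndarray:
    t_end = schedule.end_times[-1] / 60.0
    n = int(np.ceil(t_end / dt_min))
    return np.linspace(0.0, n * dt_min, n + 1)


def reference_fine_curve(
    input_function: InputFunction,
    reference_params: OneTissueParams,
    schedule: FrameSchedule,
    dt_min: float = DEFAULT_FINE_DT_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous reference-region curve C_R = K1' (C_p (*) e^{-k2' t}) on a fine grid."""
    t = _fine_grid(schedule, dt_min)
    cp = input_function(t)
    cr = reference_params.K1 * exp_conv(cp, reference_params.k2, dt_min)
    return t, cr


def simulate_reference_tac(
    input_function: InputFunction,
    reference_params: OneTissueParams,
    schedule: FrameSchedule,
    dt_min: float = DEFAULT_FINE_DT_MIN,
) -> TimeActivityCurve:
    """Frame-averaged reference-region TAC from one-tissue kinetics."""
    t, cr = reference_fine_curve(input_function, reference_params, schedule, dt_min)
    return TimeActivityCurve.from_schedule(schedule, frame_average(t, cr, schedule))


def srtm_forward_fine(
    t_fine: np.ndarray, cr_fine: np.ndarray, R1: float, k2: float, bp_nd: float
) -> np.ndarray:
    """SRTM operational equation on the fine grid."""
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if 1.0 + bp_nd <= 0:
        raise ValueError("BP_ND must exceed -1")
    dt = float(t_fine[1] - t_fine[0])
    k2a = k2 / (1.0 + bp_nd)
    return R1 * cr_fine + (k2 - R1 * k2a) * exp_conv(cr_fine, k2a, dt)


def simulate_lesion_tac_srtm(
    reference_fine: tuple[np.ndarray, np.ndarray],
    truth: KineticGroundTruth,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Forward-simulate a lesion TAC from the continuous reference curve."""
    t_fine, cr_fine = reference_fine
    ct = srtm_forward_fine(np.asarray(t_fine, float), np.asarray(cr_fine, float),
                           truth.R1, truth.k2, truth.bp_nd)
    return TimeActivityCurve.from_schedule(schedule, frame_average(t_fine, ct, schedule))


def tac_noise_sd(
    conc: np.ndarray, t_min: np.ndarray, dt_min: np.ndarray,
    noise_scale: float, half_life_min: float = GA68_HALF_LIFE_MIN,
) -> np.ndarray:
    """Frame-statistics noise law: var_i = scale^2 * C_i * e^{lambda t_i} / dt_i.

    Decay-corrected frames late in the scan and short frames carry fewer true
    counts, hence more variance.
    """
    lam = np.log(2.0) / half_life_min
    var = noise_scale**2 * np.maximum(conc, 0.0) * np.exp(lam * t_min) / dt_min
    return np.sqrt(var)


def add_tac_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    half_life_min: float = GA68_HALF_LIFE_MIN,
    seed: int | np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Add zero-mean Gaussian frame noise under the frame-statistics variance law.

    Also attaches inverse-variance fitting weights computed from the
    noiseless input (variance floored at its value for 5% of the peak, so
    near-zero early frames do not get unbounded weight), normalized to mean 1.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = tac_noise_sd(tac.conc, tac.t_min, tac.dt_min, noise_scale, half_life_min)
    noisy = tac.conc + (rng.standard_normal(tac.n_frames) * sd if noise_scale > 0 else 0.0)
    if noise_scale > 0:
        floor = tac_noise_sd(np.full_like(tac.conc, 0.05 * np.max(tac.conc)),
                             tac.t_min, tac.dt_min, noise_scale, half_life_min)
        var = np.maximum(sd, floor) ** 2
        w = 1.0 / var
        w /= w.mean()
    else:
        w = np.ones(tac.n_frames)
    return TimeActivityCurve(tac.t_min.copy(), tac.dt_min.copy(), noisy, w)
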