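"""Core containers: PET frame schedules and time-activity curves.

Conventions
-----------
* Frame schedules are stored in **seconds** post-injection (the unit in
  which acquisition protocols are written); time-activity curves carry
  frame mid-times and durations in **minutes** (the unit of kinetic rate
  constants).
* Frames must be contiguous: each frame starts where the previous one
  ends.  Gapped schedules are rejected rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GA68_HALF_LIFE_MIN = 67.71  # physical half-life of Ga-68, minutes


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous PET frame timing.

    Parameters
    ----------
    start_times : array-like
        Frame start times in seconds post-injection, strictly increasing.
    durations : array-like
        Frame durations in seconds, all positive.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.start_times, dtype=float)
        du = np.asarray(self.durations, dtype=float)
        if st.ndim != 1 or du.ndim != 1 or st.size != du.size or st.size == 0:
            raise ValueError("start_times and durations must be equal-length 1-D arrays")
        if np.any(du <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(st) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if not np.allclose(st[1:], st[:-1] + du[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous (next start = previous start + duration)")
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "durations", du)

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.start_times + 0.5 * self.durations) / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations / 60.0

    @property
    def total_seconds(self) -> float:
        return float(self.end_times[-1] - self.start_times[0])

    @classmethod
    def dynamic_55frame(cls) -> "FrameSchedule":
        """The 40-min dynamic protocol: 15 x 20 s, 15 x 40 s, 25 x 60 s (55 frames, 2400 s)."""
        durations = np.concatenate([np.full(15, 20.0), np.full(15, 40.0), np.full(25, 60.0)])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)


# backwards-friendly alias used by presets and the CLI
paper55 = FrameSchedule.dynamic_55frame


@dataclass
class TimeActivityCurve:
    """Regional tracer concentration per PET frame.

    Attributes
    ----------
    t_min : frame mid-times, minutes post-injection
    dt_min : frame durations, minutes
    conc : activity concentration, Bq/ml
    weights : inverse-variance fitting weights (unitless, mean 1 when set)
    """

    t_min: np.ndarray
    dt_min: np.ndarray
    conc: np.ndarray
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.dt_min = np.asarray(self.dt_min, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        n = self.t_min.size
        if self.dt_min.size != n or self.conc.size != n:
            raise ValueError("t_min, dt_min and conc must have equal length")
        if np.any(self.dt_min <= 0):
            raise ValueError("frame durations must be positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != n:
                raise ValueError("weights length mismatch")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.t_min.size

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, conc, weights=None) -> "TimeActivityCurve":
        return cls(schedule.mid_times_min, schedule.durations_min, conc, weights)

    def copy_with(self, conc=None, weights=None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.t_min.copy(),
            self.dt_min.copy(),
            self.conc.copy() if conc is None else np.asarray(conc, float),
            self.weights.copy() if (weights is None and self.weights is not None) else weights,
        )


def frame_average(t_fine: np.ndarray, c_fine: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a continuous-time curve over each frame interval.

    PET frames integrate counts over their duration, so frame values are
    time-averages (trapezoidal on the fine grid, with interpolated frame
    endpoints), not point samples at mid-time.
    """
    starts_min = schedule.start_times / 60.0
    ends_min = schedule.end_times / 60.0
    if starts_min[0] < t_fine[0] - 1e-12 or ends_min[-1] > t_fine[-1] + 1e-9:
        raise ValueError("fine grid does not cover the frame schedule")
    out = np.empty(schedule.n_frames)
    for i, (a, b) in enumerate(zip(starts_min, ends_min)):
        inside = t_fine[(t_fine > a) & (t_fine < b)]
        ts = np.concatenate([[a], inside, [b]])
        cs = np.interp(ts, t_fine, c_fine)
        out[i] = np.trapezoid(cs, ts) / (b - a)
    return out
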