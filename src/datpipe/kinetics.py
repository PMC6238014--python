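"""Reference-tissue kinetics for synthetic time-activity curves.

The reference (cerebellum) curve is a gamma-variate bolus response,
C_ref(t) = A * t**alpha * exp(-t/beta).  Target-region curves follow the
simplified reference tissue model (SRTM),

    C_T(t) = R1*C_ref(t) + (k2 - R1*k2a) * [C_ref (x) exp(-k2a*t)](t),

with k2a = k2/(1 + BP_ND), so the generated pair has a known ground-truth
distribution volume ratio DVR = 1 + BP_ND.  Convolution is done on a fine
uniform grid (1 s by default) before averaging over the acquisition frames.

Default rate constants (R1 = 0.9, k2 = 0.5 /min) and the gamma-variate shape
(alpha = 0.3, beta = 25 min, peak at 7.5 min) are implementation choices for
a fast-kinetics DAT tracer, tuned so that the target/reference ratio reaches
a pseudo-equilibrium plateau by ~50 min and reference-Logan estimates are
essentially unbiased on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FrameSchedule

__all__ = [
    "TimeActivityCurve",
    "KineticParameters",
    "GammaVariateInput",
    "DEFAULT_REFERENCE_MODEL",
    "DEFAULT_KINETICS",
    "simulate_reference_tac",
    "srtm_target_tac",
    "srtm_continuous",
    "fine_grid",
]

#: fine-grid step for convolution and frame averaging, minutes (= 1 s)
FINE_DT_MIN = 1.0 / 60.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional mean activity per frame, at frame mid-times (minutes)."""

    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("TAC times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_min.size

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times_min, self.values * factor)


@dataclass(frozen=True)
class KineticParameters:
    """SRTM parameters: delivery ratio R1, reference efflux k2 (1/min), true BP_ND."""

    r1: float = 0.9
    k2: float = 0.5
    bp_nd_true: float = 3.5

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp_nd_true < 0:
            raise ValueError("bp_nd_true must be non-negative")

    @property
    def k2a(self) -> float:
        """Apparent target efflux rate, k2/(1 + BP_ND), 1/min."""
        return self.k2 / (1.0 + self.bp_nd_true)

    def with_bp(self, bp_nd_true: float) -> "KineticParameters":
        return KineticParameters(self.r1, self.k2, bp_nd_true)


@dataclass(frozen=True)
class GammaVariateInput:
    """Gamma-variate reference curve C(t) = amplitude * t**shape * exp(-t/decay_min).

    amplitude is in arbitrary activity units (kBq/mL-like); shape is unitless;
    decay_min is the exponential decay constant in minutes.  The curve is zero
    at t = 0, rises to a single peak at shape*decay_min, then declines
    monotonically.
    """

    amplitude: float = 70.0
    shape: float = 0.3
    decay_min: float = 25.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape <= 0 or self.decay_min <= 0:
            raise ValueError("shape and decay_min must be positive")

    @property
    def peak_time_min(self) -> float:
        return self.shape * self.decay_min

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = self.amplitude * t[pos] ** self.shape * np.exp(-t[pos] / self.decay_min)
        return out


DEFAULT_REFERENCE_MODEL = GammaVariateInput()
DEFAULT_KINETICS = KineticParameters()


def fine_grid(schedule: FrameSchedule, dt_min: float = FINE_DT_MIN) -> np.ndarray:
    """Uniform time grid (minutes) covering the acquisition, step dt_min."""
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    end = schedule.ends_s[-1] / 60.0
    return np.arange(0.0, end + dt_min / 2, dt_min)


def frame_average(
    tgrid_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule
) -> TimeActivityCurve:
    """Average a continuous curve over each frame interval (trapezoid rule)."""
    dt = float(tgrid_min[1] - tgrid_min[0])
    values = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.starts_s / 60.0, schedule.ends_s / 60.0)):
        i0, i1 = int(round(s / dt)), int(round(e / dt))
        if i1 <= i0 or i1 >= tgrid_min.size:
            raise ValueError("fine grid too coarse for frame averaging")
        seg = curve[i0 : i1 + 1]
        values[i] = np.trapezoid(seg, dx=dt) / (e - s)
    return TimeActivityCurve(schedule.mid_min, values)


def simulate_reference_tac(
    model: GammaVariateInput,
    schedule: FrameSchedule,
    dt_min: float = FINE_DT_MIN,
) -> TimeActivityCurve:
    """Frame-averaged reference-region TAC from the continuous input model.

    A zero-amplitude model yields an all-zero TAC (negative amplitude is
    rejected at model construction).
    """
    tgrid = fine_grid(schedule, dt_min)
    return frame_average(tgrid, model(tgrid), schedule)


def srtm_continuous(
    model: GammaVariateInput,
    params: KineticParameters,
    tgrid_min: np.ndarray,
) -> np.ndarray:
    """SRTM target curve on a uniform fine grid (minutes)."""
    dt = np.diff(tgrid_min)
    if tgrid_min.size < 2 or not np.allclose(dt, dt[0]):
        raise ValueError("srtm_continuous requires a uniform time grid")
    step = float(dt[0])
    cref = model(tgrid_min)
    kernel = np.exp(-params.k2a * tgrid_min)
    conv = np.convolve(cref, kernel)[: tgrid_min.size] * step
    ct = params.r1 * cref + (params.k2 - params.r1 * params.k2a) * conv
    if not np.all(np.isfinite(ct)):
        raise ValueError("non-finite SRTM convolution; check grid configuration")
    return ct


def srtm_target_tac(
    model: GammaVariateInput,
    params: KineticParameters,
    schedule: FrameSchedule,
    dt_min: float = FINE_DT_MIN,
) -> TimeActivityCurve:
    """Frame-averaged SRTM target TAC with ground-truth DVR = 1 + bp_nd_true."""
    tgrid = fine_grid(schedule, dt_min)
    return frame_average(tgrid, srtm_continuous(model, params, tgrid), schedule)
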