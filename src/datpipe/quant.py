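"""Outcome measures: reference-Logan BP_ND, SUVR, SUR, weighted striatum.

The reference Logan plot regresses

    y(t) = int_0^t C_T / C_T(t)   against   x(t) = int_0^t C_ref / C_T(t)

over frames with mid-time inside the regression window (27-75 min by
default); the slope is the distribution volume ratio (DVR) and
BP_ND = DVR - 1.  The variant with the k2 term uses
x(t) = [int_0^t C_ref + C_ref(t)/k2] / C_T(t) with k2 fixed from the
simplified reference tissue model.  Integrals are trapezoidal, anchored at
zero activity at injection, evaluated at frame mid-times.  The regression
is unweighted ordinary least squares.

SUVR is the VOI/reference mean ratio on a static image; SUR is
(VOI - background)/background, the SPECT analogue (SUR = SUVR - 1 on
identical inputs).  Whole-striatum values combine caudate and putamen by
their fixed delineation volumes (2.0 and 2.5 mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .kinetics import TimeActivityCurve

__all__ = [
    "LoganConfig",
    "StriatalWeights",
    "QuantResult",
    "cumulative_integral",
    "reference_logan_dvr",
    "bp_nd_from_dvr",
    "suvr",
    "sur",
    "weighted_striatal",
]


@dataclass(frozen=True)
class LoganConfig:
    """Reference Logan settings: regression window (minutes) and k2 variant."""

    t_star: float = 27.0
    end: float = 75.0
    include_k2_term: bool = False
    k2_ref: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.t_star < self.end):
            raise ValueError("require 0 < t_star < end")
        if self.include_k2_term and (self.k2_ref is None or self.k2_ref <= 0):
            raise ValueError("k2_ref must be positive when include_k2_term is set")


@dataclass(frozen=True)
class StriatalWeights:
    """Delineation volumes used as striatal combination weights, mL."""

    v_caudate: float = 2.0
    v_putamen: float = 2.5

    def __post_init__(self) -> None:
        if self.v_caudate <= 0 or self.v_putamen <= 0:
            raise ValueError("striatal weights must be positive")


@dataclass
class QuantResult:
    """Per-region, per-side outcome values with VOI bookkeeping."""

    region: str
    side: str
    bp_nd: Optional[float] = None
    dvr: Optional[float] = None
    suvr: Optional[float] = None
    sur: Optional[float] = None
    volume_ml: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bp_nd is not None and self.dvr is not None:
            if not np.isclose(self.dvr, self.bp_nd + 1.0):
                raise ValueError("dvr must equal bp_nd + 1")


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running trapezoidal integral of a TAC from injection, at frame mid-times.

    Activity is taken as zero at t = 0 (bolus injection), so the first
    trapezoid spans [0, t_mid(0)].
    """
    if len(tac) < 2:
        raise ValueError("cumulative integral requires at least 2 frames")
    t = np.concatenate([[0.0], tac.times_min])
    v = np.concatenate([[0.0], tac.values])
    return np.cumsum(np.diff(t) * (v[1:] + v[:-1]) / 2.0)


def reference_logan_dvr(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    cfg: LoganConfig = LoganConfig(),
) -> tuple[float, dict]:
    """Reference Logan DVR as the OLS slope over the linear late phase.

    Returns (dvr, diagnostics) where diagnostics holds the intercept, the
    squared correlation of the Logan plot, and the number of points used.
    """
    if not np.array_equal(target.times_min, ref.times_min):
        raise ValueError("target and reference TACs must share the frame grid")
    sel = (target.times_min >= cfg.t_star) & (target.times_min <= cfg.end)
    if sel.sum() < 2:
        raise ValueError("need at least 2 frames with mid-time inside the Logan window")
    ct = target.values[sel]
    if np.any(ct <= 0):
        raise ValueError("non-positive target activity inside the Logan window")
    int_t = cumulative_integral(target)[sel]
    int_r = cumulative_integral(ref)[sel]
    y = int_t / ct
    if cfg.include_k2_term:
        x = (int_r + ref.values[sel] / cfg.k2_ref) / ct
    else:
        x = int_r / ct
    if np.ptp(x) <= 0:
        raise ValueError("degenerate Logan abscissa (no spread)")
    slope, intercept, r_value, _, stderr = sps.linregress(x, y)
    diagnostics = {
        "intercept": float(intercept),
        "r_squared": float(r_value**2),
        "n_points": int(sel.sum()),
        "slope_stderr": float(stderr),
    }
    return float(slope), diagnostics


def bp_nd_from_dvr(dvr: float) -> float:
    """BP_ND = DVR - 1."""
    if not np.isfinite(dvr):
        raise ValueError("DVR must be finite")
    return float(dvr) - 1.0


def suvr(static: np.ndarray, voi, ref_voi) -> float:
    """Mean VOI activity divided by mean reference-VOI activity on a static image.

    Masks may be VoiMask objects or plain boolean arrays.
    """
    from .voi import VoiMask

    voi_arr = voi.data if isinstance(voi, VoiMask) else np.asarray(voi, dtype=bool)
    ref_arr = (
        ref_voi.data if isinstance(ref_voi, VoiMask) else np.asarray(ref_voi, dtype=bool)
    )
    if not voi_arr.any() or not ref_arr.any():
        raise ValueError("VOI masks must be nonempty")
    ref_mean = float(static[ref_arr].mean())
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(static[voi_arr].mean()) / ref_mean


def sur(voi_mean: float, background_mean: float) -> float:
    """Specific uptake ratio, (VOI - background)/background."""
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    return (voi_mean - background_mean) / background_mean


def weighted_striatal(
    value_caudate: float,
    value_putamen: float,
    weights: StriatalWeights = StriatalWeights(),
) -> float:
    """Volume-weighted caudate/putamen combination for whole-striatum values."""
    w = weights
    return (value_caudate * w.v_caudate + value_putamen * w.v_putamen) / (
        w.v_caudate + w.v_putamen
    )
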