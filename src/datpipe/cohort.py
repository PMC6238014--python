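"""Synthetic HC/PS cohorts with known regional binding ground truth.

Per-subject true BP_ND values are drawn from group-specific normal
distributions whose defaults are calibrated to published healthy-control and
early-parkinsonian FE-PE2I ranges (HC caudate 2.93 +/- 0.46, putamen
3.78 +/- 0.46, SN 0.72 +/- 0.07; PS caudate 2.29 +/- 0.80, putamen
1.98 +/- 1.07, SN 0.60 +/- 0.10).  Patients with lateralized symptoms get a
multiplicative asymmetry split symmetrically around the drawn subject mean:
the hemisphere contralateral to the clinical side is reduced by offset/2 and
the ipsilateral one raised by offset/2, so the left/right average preserves
the drawn value.  The nigral asymmetry is attenuated (weaker clinical
laterality of midbrain binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_REFERENCE_MODEL,
    GammaVariateInput,
    KineticParameters,
    TimeActivityCurve,
    fine_grid,
    frame_average,
    simulate_reference_tac,
    srtm_continuous,
)
from .schedule import FrameSchedule, make_default_schedule

__all__ = ["CohortSpec", "generate_cohort", "DEFAULT_HC_BP", "DEFAULT_PS_BP"]

DEFAULT_HC_BP = {"caudate": (2.93, 0.46), "putamen": (3.78, 0.46), "SN": (0.72, 0.07)}
DEFAULT_PS_BP = {"caudate": (2.29, 0.80), "putamen": (1.98, 1.07), "SN": (0.60, 0.10)}

#: clinical-side frequencies among patients (right, left, symmetric)
DEFAULT_SIDE_PROBS = (12 / 22, 8 / 22, 2 / 22)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, regional BP distributions, lateralization, noise and seed."""

    n_hc: int = 28
    n_ps: int = 22
    hc_bp: dict = field(default_factory=lambda: dict(DEFAULT_HC_BP))
    ps_bp: dict = field(default_factory=lambda: dict(DEFAULT_PS_BP))
    lateralization_offset: float = 0.3
    sn_offset_factor: float = 0.25
    side_probs: tuple = DEFAULT_SIDE_PROBS
    tac_noise_scale: float = 0.0
    r1: float = 0.9
    k2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_ps < 2:
            raise ValueError("group sizes must be at least 2")
        for dist in (self.hc_bp, self.ps_bp):
            for region, (mean, sd) in dist.items():
                if mean < 0 or sd < 0:
                    raise ValueError(f"invalid distribution for {region!r}")
        if set(self.hc_bp) != set(self.ps_bp):
            raise ValueError("HC and PS distributions must cover the same regions")
        if not (0 <= self.lateralization_offset < 2):
            raise ValueError("lateralization offset out of range")
        if abs(sum(self.side_probs) - 1.0) > 1e-9:
            raise ValueError("side probabilities must sum to 1")


def _noisy(
    tac: TimeActivityCurve,
    schedule: FrameSchedule,
    scale: float,
    rng: np.random.Generator,
) -> TimeActivityCurve:
    if scale == 0:
        return tac
    sd = scale * np.sqrt(np.clip(tac.values, 0.0, None) / schedule.durations_min)
    return TimeActivityCurve(tac.times_min, tac.values + rng.normal(0.0, 1.0, len(tac)) * sd)


def generate_cohort(
    spec: CohortSpec,
    model: GammaVariateInput = DEFAULT_REFERENCE_MODEL,
    schedule: FrameSchedule | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort and simulate per-subject regional TACs.

    Returns (truth, tacs): truth is a tidy table with one row per
    subject/region/side holding group, clinical side and the true BP_ND;
    tacs maps (subject, region, side) -> TimeActivityCurve, plus
    (subject, "reference", "") for each subject's cerebellum curve.
    Fully reproducible from the spec seed.
    """
    schedule = schedule or make_default_schedule()
    rng = np.random.default_rng(spec.seed)
    tgrid = fine_grid(schedule)
    regions = sorted(spec.hc_bp)

    rows = []
    tacs: dict = {}
    subjects = [("HC", i) for i in range(spec.n_hc)] + [
        ("PS", i) for i in range(spec.n_ps)
    ]
    for group, i in subjects:
        subject = f"{group.lower()}{i:03d}"
        if group == "PS":
            clinical_side = rng.choice(
                ["right", "left", "symmetric"], p=spec.side_probs
            )
        else:
            clinical_side = "none"
        ref_tac = _noisy(
            simulate_reference_tac(model, schedule), schedule, spec.tac_noise_scale, rng
        )
        tacs[(subject, "reference", "")] = ref_tac
        for region in regions:
            mean, sd = (spec.hc_bp if group == "HC" else spec.ps_bp)[region]
            # floor keeps binding positive: even severe disease retains some DAT
            bp_mean = max(0.05, rng.normal(mean, sd)) if sd > 0 else mean
            offset = 0.0
            if group == "PS" and clinical_side in ("left", "right"):
                offset = spec.lateralization_offset
                if region == "SN":
                    offset *= spec.sn_offset_factor
            contra = "right" if clinical_side == "left" else "left"
            for side in ("L", "R"):
                is_contra = side == ("L" if contra == "left" else "R")
                factor = 1.0 - offset / 2.0 if is_contra else 1.0 + offset / 2.0
                bp_true = bp_mean * factor if offset else bp_mean
                params = KineticParameters(spec.r1, spec.k2, bp_true)
                tac = frame_average(
                    tgrid, srtm_continuous(model, params, tgrid), schedule
                )
                tacs[(subject, region, side)] = _noisy(
                    tac, schedule, spec.tac_noise_scale, rng
                )
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "clinical_side": clinical_side,
                        "region": region,
                        "side": side,
                        "bp_nd_true": bp_true,
                    }
                )
    return pd.DataFrame(rows), tacs
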