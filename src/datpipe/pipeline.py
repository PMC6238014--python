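"""Subject- and cohort-level orchestration.

quantify_subject runs the full image-level chain on one subject: frame
summation, activity-guided VOI delineation (fixed-volume top-k for caudate
and putamen, threshold segmentation for the substantia nigra), TAC
extraction, reference-Logan BP_ND, windowed SUVR on a re-delineated static
image, and SPECT SUR against the occipital background.  Cohort helpers run
the TAC-level equivalent over a generated cohort and compute the group
report (effect sizes, agreement, diagnostic accuracy, lateralization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import TimeActivityCurve
from .quant import (
    LoganConfig,
    QuantResult,
    StriatalWeights,
    bp_nd_from_dvr,
    reference_logan_dvr,
    suvr as suvr_ratio,
    sur,
    weighted_striatal,
)
from .schedule import FrameSchedule
from .stats import (
    glass_delta,
    icc_consistency,
    laterality_concordance,
    lr_average,
    mann_whitney_exact,
    roc_auc,
)
from .voi import (
    LabelVolume,
    SnSearchSpec,
    VoiMask,
    extract_tac,
    sn_threshold_voi,
    sum_frames,
    topk_within_mask,
)

__all__ = [
    "quantify_subject",
    "windowed_suvr",
    "quantify_cohort_tacs",
    "cohort_statistics",
    "results_to_frame",
]

BP_WINDOW = (27.0, 75.0)
SUVR_WINDOW = (51.0, 75.0)


def results_to_frame(results: list[QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "region": r.region,
            "side": r.side,
            "bp_nd": r.bp_nd,
            "dvr": r.dvr,
            "suvr": r.suvr,
            "sur": r.sur,
            "volume_ml": r.volume_ml,
        }
        row.update({f"diag_{k}": v for k, v in r.diagnostics.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _with_context(region: str, side: str):
    """Decorator-ish helper: re-raise stage errors with region/side context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"{region}/{side}: {exc}") from exc

    return _Ctx()


def _delineate_striatal(
    summed: np.ndarray, labels: LabelVolume, weights: StriatalWeights
) -> dict[tuple[str, str], VoiMask]:
    vois = {}
    for region, target in (("caudate", weights.v_caudate), ("putamen", weights.v_putamen)):
        for side in ("L", "R"):
            with _with_context(region, side):
                vois[(region, side)] = topk_within_mask(
                    summed, labels.mask(f"{region}_{side}"), target
                )
    return vois


def _delineate_sn(
    summed: np.ndarray,
    labels: LabelVolume,
    ref_mean: float,
    sn_spec: SnSearchSpec,
) -> dict[str, VoiMask]:
    vois = {}
    for side in ("L", "R"):
        with _with_context("SN", side):
            vois[side] = sn_threshold_voi(
                summed, labels.mask(f"SN_{side}"), ref_mean, sn_spec
            )
    return vois


def quantify_subject(
    dyn: np.ndarray | None,
    labels: LabelVolume,
    schedule: FrameSchedule | None = None,
    spect: np.ndarray | None = None,
    logan_cfg: LoganConfig = LoganConfig(),
    weights: StriatalWeights = StriatalWeights(),
    sn_spec: SnSearchSpec = SnSearchSpec(),
    bp_window: tuple = BP_WINDOW,
    suvr_window: tuple = SUVR_WINDOW,
) -> list[QuantResult]:
    """Quantify one subject; any of the dynamic-PET or SPECT paths may run.

    The dynamic path needs caudate/putamen/cerebellum labels (SN is optional:
    missing seed labels simply omit the SN rows); the SPECT path needs an
    occipital background label.  Results carry VOI volumes and fit
    diagnostics; whole-striatum rows combine caudate and putamen by the
    delineation volumes.
    """
    results: list[QuantResult] = []
    if dyn is not None:
        if schedule is None:
            raise ValueError("dynamic path requires a frame schedule")
        cereb = labels.mask("cerebellum")
        ref_tac = extract_tac(dyn, cereb, schedule)

        # BP_ND path: delineate on the late summed image, fit reference Logan
        summed_bp = sum_frames(dyn, schedule, bp_window)
        vois = _delineate_striatal(summed_bp, labels, weights)
        sn_available = labels.has("SN_L") and labels.has("SN_R")
        if sn_available:
            ref_mean_bp = float(summed_bp[cereb.data].mean())
            for side, voi in _delineate_sn(summed_bp, labels, ref_mean_bp, sn_spec).items():
                vois[("SN", side)] = voi

        # SUVR path: re-delineate on the static (51-75 min) summed image
        summed_static = sum_frames(dyn, schedule, suvr_window)
        static_vois = _delineate_striatal(summed_static, labels, weights)
        if sn_available:
            ref_mean_static = float(summed_static[cereb.data].mean())
            for side, voi in _delineate_sn(
                summed_static, labels, ref_mean_static, sn_spec
            ).items():
                static_vois[("SN", side)] = voi

        per_side: dict[tuple[str, str], QuantResult] = {}
        for (region, side), voi in vois.items():
            with _with_context(region, side):
                tac = extract_tac(dyn, voi, schedule)
                dvr, diag = reference_logan_dvr(tac, ref_tac, logan_cfg)
                diag["voxel_count"] = voi.voxel_count
                if voi.provenance.startswith("sn_threshold"):
                    diag["a_th"] = float(voi.provenance.split("=")[1])
                res = QuantResult(
                    region=region,
                    side=side,
                    bp_nd=bp_nd_from_dvr(dvr),
                    dvr=dvr,
                    volume_ml=voi.volume_ml,
                    diagnostics=diag,
                )
            if (region, side) in static_vois:
                with _with_context(region, side):
                    res.suvr = suvr_ratio(summed_static, static_vois[(region, side)], cereb)
            per_side[(region, side)] = res
            results.append(res)
        for side in ("L", "R"):
            caud, put = per_side[("caudate", side)], per_side[("putamen", side)]
            results.append(
                QuantResult(
                    region="striatum",
                    side=side,
                    bp_nd=weighted_striatal(caud.bp_nd, put.bp_nd, weights),
                    dvr=weighted_striatal(caud.dvr, put.dvr, weights),
                    suvr=weighted_striatal(caud.suvr, put.suvr, weights),
                    volume_ml=weights.v_caudate + weights.v_putamen,
                    diagnostics={"combination": "volume-weighted caudate+putamen"},
                )
            )

    if spect is not None:
        bg = labels.mask("occipital")
        bg_mean = float(spect[bg.data].mean())
        spect_side: dict[tuple[str, str], float] = {}
        for region in ("caudate", "putamen"):
            for side in ("L", "R"):
                with _with_context(region, side):
                    voi = labels.mask(f"{region}_{side}")
                    value = sur(float(spect[voi.data].mean()), bg_mean)
                spect_side[(region, side)] = value
                results.append(
                    QuantResult(
                        region=region, side=side, sur=value, volume_ml=voi.volume_ml
                    )
                )
        for side in ("L", "R"):
            results.append(
                QuantResult(
                    region="striatum",
                    side=side,
                    sur=weighted_striatal(
                        spect_side[("caudate", side)],
                        spect_side[("putamen", side)],
                        weights,
                    ),
                    diagnostics={"combination": "volume-weighted caudate+putamen"},
                )
            )
    return results


def windowed_suvr(
    tac: TimeActivityCurve,
    ref: TimeActivityCurve,
    schedule: FrameSchedule,
    window_min: tuple = SUVR_WINDOW,
) -> float:
    """SUVR from TACs: duration-weighted window mean ratio (static-scan analogue)."""
    idx = schedule.frames_in_window(*window_min)
    durs = schedule.durations_s[idx]
    num = float(np.sum(tac.values[idx] * durs) / durs.sum())
    den = float(np.sum(ref.values[idx] * durs) / durs.sum())
    if den <= 0:
        raise ValueError("non-positive reference activity in the SUVR window")
    return num / den


def quantify_cohort_tacs(
    truth: pd.DataFrame,
    tacs: dict,
    schedule: FrameSchedule,
    logan_cfg: LoganConfig = LoganConfig(),
    suvr_window: tuple = SUVR_WINDOW,
) -> pd.DataFrame:
    """TAC-level cohort quantification: reference-Logan BP_ND and windowed SUVR
    for every subject/region/side row of the generated cohort."""
    rows = []
    for (subject, region, side), tac in tacs.items():
        if region == "reference":
            continue
        ref = tacs[(subject, "reference", "")]
        dvr, diag = reference_logan_dvr(tac, ref, logan_cfg)
        rows.append(
            {
                "subject": subject,
                "region": region,
                "side": side,
                "bp_nd": bp_nd_from_dvr(dvr),
                "suvr": windowed_suvr(tac, ref, schedule, suvr_window),
                "logan_r_squared": diag["r_squared"],
            }
        )
    measured = pd.DataFrame(rows)
    meta = truth[["subject", "group", "clinical_side"]].drop_duplicates()
    merged = measured.merge(meta, on="subject", how="left")
    truth_cols = truth[["subject", "region", "side", "bp_nd_true"]]
    return merged.merge(truth_cols, on=["subject", "region", "side"], how="left")


def _lr_table(measured: pd.DataFrame, measure: str) -> pd.DataFrame:
    """One row per subject/region with left, right and their average."""
    wide = measured.pivot_table(
        index=["subject", "group", "clinical_side", "region"],
        columns="side",
        values=measure,
    ).reset_index()
    wide["mean_lr"] = [lr_average(l, r) for l, r in zip(wide["L"], wide["R"])]
    return wide


def cohort_statistics(
    measured: pd.DataFrame,
    measures: tuple = ("bp_nd", "suvr"),
    seed: int = 0,
) -> dict:
    """Group-comparison report over a quantified cohort.

    Per region and measure: group means/SDs of the left/right-averaged
    values, Glass's delta, exact Mann-Whitney p, and ROC AUC with bootstrap
    CI (lower value indicates disease).  Adds the consistency ICC between
    the two measures and, for lateralized patients, the contralateral
    concordance of the lower-binding hemisphere.
    """
    groups = measured["group"].unique()
    if not {"HC", "PS"}.issubset(groups):
        raise ValueError("cohort must contain both HC and PS groups")
    report: dict = {"per_region": [], "icc": [], "laterality": []}
    for measure in measures:
        if measure not in measured.columns:
            continue
        wide = _lr_table(measured, measure)
        for region in sorted(wide["region"].unique()):
            sub = wide[wide["region"] == region]
            hc = sub.loc[sub["group"] == "HC", "mean_lr"].to_numpy()
            ps = sub.loc[sub["group"] == "PS", "mean_lr"].to_numpy()
            auc, ci = roc_auc(
                np.concatenate([np.zeros(hc.size), np.ones(ps.size)]),
                np.concatenate([hc, ps]),
                direction="lower",
                seed=seed,
            )
            report["per_region"].append(
                {
                    "measure": measure,
                    "region": region,
                    "hc_mean": hc.mean(),
                    "hc_sd": hc.std(ddof=1),
                    "ps_mean": ps.mean(),
                    "ps_sd": ps.std(ddof=1),
                    "glass_delta": glass_delta(hc, ps),
                    "mann_whitney_p": mann_whitney_exact(hc, ps, seed=seed),
                    "auc": auc,
                    "auc_ci_low": ci[0],
                    "auc_ci_high": ci[1],
                }
            )
        ps_wide = wide[(wide["group"] == "PS")]
        lateralized = ps_wide[ps_wide["clinical_side"].isin(["left", "right"])]
        for region in sorted(lateralized["region"].unique()):
            sub = lateralized[lateralized["region"] == region]
            report["laterality"].append(
                {
                    "measure": measure,
                    "region": region,
                    "concordance_pct": laterality_concordance(
                        sub["L"], sub["R"], sub["clinical_side"]
                    ),
                    "n": len(sub),
                }
            )
    if len(measures) >= 2 and all(m in measured.columns for m in measures[:2]):
        m1 = _lr_table(measured, measures[0])
        m2 = _lr_table(measured, measures[1])
        joined = m1.merge(
            m2, on=["subject", "group", "clinical_side", "region"], suffixes=("_1", "_2")
        )
        for region in sorted(joined["region"].unique()):
            sub = joined[joined["region"] == region]
            report["icc"].append(
                {
                    "measures": f"{measures[0]}~{measures[1]}",
                    "region": region,
                    "cicc": icc_consistency(sub["mean_lr_1"], sub["mean_lr_2"]),
                }
            )
    return report
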