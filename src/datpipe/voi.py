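"""Activity-guided VOI construction on voxel grids.

Anatomical label volumes (from an upstream MRI segmentation) restrict where
activity-based delineation may select voxels.  Striatal VOIs are fixed-volume
top-k selections inside the anatomical mask on a summed late image; the
substantia nigra VOI is a half-maximum-style threshold segmentation,
A_th = f*(A_max - A_ref) + A_ref with f = 0.5, inside a small search box
centred on the seed's centre of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "LabelVolume",
    "VoiMask",
    "SnSearchSpec",
    "SegmentationError",
    "NoSpecificBindingError",
    "sum_frames",
    "topk_within_mask",
    "sn_threshold_voi",
    "center_of_mass",
    "extract_tac",
]

#: canonical label coding shared by the phantom generator and the pipeline
DEFAULT_LABELS = {
    "background": 0,
    "caudate_L": 1,
    "caudate_R": 2,
    "putamen_L": 3,
    "putamen_R": 4,
    "cerebellum": 5,
    "SN_L": 6,
    "SN_R": 7,
    "occipital": 8,
}


class SegmentationError(ValueError):
    """Anatomical mask too small for the requested fixed-volume selection."""


class NoSpecificBindingError(ValueError):
    """In-box maximum does not exceed the reference level; no specific binding."""


@dataclass(frozen=True)
class LabelVolume:
    """Integer-coded anatomical regions on a voxel grid.

    data holds one label code per voxel; labels maps region name -> code.
    voxel_size_mm is isotropic.
    """

    data: np.ndarray
    voxel_size_mm: float
    labels: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.data < 0):
            raise ValueError("labels must be non-negative")

    def has(self, name: str) -> bool:
        return name in self.labels and bool(np.any(self.data == self.labels[name]))

    def mask(self, name: str) -> "VoiMask":
        if name not in self.labels:
            raise KeyError(f"unknown label {name!r}")
        m = self.data == self.labels[name]
        if not m.any():
            raise ValueError(f"label {name!r} has no voxels")
        return VoiMask(m, self.voxel_size_mm, provenance=f"label:{name}")


@dataclass(frozen=True)
class VoiMask:
    """Boolean voxel mask with volume bookkeeping and a provenance tag."""

    data: np.ndarray
    voxel_size_mm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_size_mm**3 / 1000.0


@dataclass(frozen=True)
class SnSearchSpec:
    """Substantia-nigra search box (mm) and threshold fraction f."""

    box_mm: tuple = (17.0, 13.0, 10.0)
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.box_mm) or len(self.box_mm) != 3:
            raise ValueError("box dimensions must be three positive lengths")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold fraction must lie in (0, 1)")


def sum_frames(
    dyn: np.ndarray, schedule: FrameSchedule, window_min: tuple[float, float]
) -> np.ndarray:
    """Duration-weighted time average of the frames fully inside the window.

    Equivalent, up to the constant total duration, to the duration-weighted
    frame sum; partial frames are an error.
    """
    if dyn.ndim != 4 or dyn.shape[3] != schedule.n_frames:
        raise ValueError("dynamic image must be 4-D with one volume per frame")
    idx = schedule.frames_in_window(*window_min)
    durs = schedule.durations_s[idx]
    return np.tensordot(dyn[..., idx], durs, axes=([3], [0])) / durs.sum()


def topk_within_mask(
    image: np.ndarray, mask: VoiMask, target_volume_ml: float
) -> VoiMask:
    """Select the k hottest voxels inside the mask, k = round(V/voxel volume).

    Ties are broken by ascending (z, y, x) voxel index so the selection is
    deterministic.  Raises SegmentationError when the anatomical mask holds
    fewer than k voxels (the upstream-segmentation failure mode).
    """
    if image.shape != mask.data.shape:
        raise ValueError("image and mask shapes differ")
    voxel_ml = mask.voxel_size_mm**3 / 1000.0
    k = int(round(target_volume_ml / voxel_ml))
    if k < 1:
        raise ValueError("target volume smaller than one voxel")
    coords = np.argwhere(mask.data)
    if coords.shape[0] < k:
        raise SegmentationError(
            f"mask holds {coords.shape[0]} voxels but k={k} requested"
        )
    vals = image[mask.data]
    xs, ys, zs = coords[:, 0], coords[:, 1], coords[:, 2]
    order = np.lexsort((xs, ys, zs, -vals))[:k]
    out = np.zeros_like(mask.data)
    out[tuple(coords[order].T)] = True
    return VoiMask(out, mask.voxel_size_mm, provenance=f"topk:{target_volume_ml}mL")


def center_of_mass(mask: VoiMask) -> tuple[int, int, int]:
    """Unweighted centroid of the true voxels, rounded to the nearest voxel."""
    coords = np.argwhere(mask.data)
    if coords.shape[0] == 0:
        raise ValueError("empty mask has no centre of mass")
    return tuple(int(c) for c in np.rint(coords.mean(axis=0)))


def sn_threshold_voi(
    image: np.ndarray,
    sn_seed: VoiMask,
    ref_mean: float,
    spec: SnSearchSpec = SnSearchSpec(),
) -> VoiMask:
    """Threshold segmentation inside a box centred on the seed's mass centre.

    The box half-widths (mm) are converted to voxels by rounding and the box
    is clipped at the grid edges.  The VOI is every in-box voxel with
    intensity >= A_th = f*(A_max - A_ref) + A_ref; the inclusive comparison
    guarantees the maximum voxel is included.
    """
    if image.shape != sn_seed.data.shape:
        raise ValueError("image and seed mask shapes differ")
    com = center_of_mass(sn_seed)
    half_vox = [
        int(round((d / 2.0) / sn_seed.voxel_size_mm)) for d in spec.box_mm
    ]
    lo = [max(0, c - h) for c, h in zip(com, half_vox)]
    hi = [min(s, c + h + 1) for c, h, s in zip(com, half_vox, image.shape)]
    box = np.zeros_like(sn_seed.data)
    box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    a_max = float(image[box].max())
    if a_max <= ref_mean:
        raise NoSpecificBindingError(
            f"in-box maximum {a_max:.4g} does not exceed reference level {ref_mean:.4g}"
        )
    a_th = spec.threshold_fraction * (a_max - ref_mean) + ref_mean
    out = box & (image >= a_th)
    return VoiMask(
        out,
        sn_seed.voxel_size_mm,
        provenance=f"sn_threshold:A_th={a_th:.4g}",
    )


def extract_tac(
    dyn: np.ndarray, mask: VoiMask, schedule: FrameSchedule
) -> TimeActivityCurve:
    """Per-frame mean over the mask, paired with frame mid-times."""
    if dyn.ndim != 4 or dyn.shape[:3] != mask.data.shape:
        raise ValueError("dynamic image and mask dimensions do not match")
    if dyn.shape[3] != schedule.n_frames:
        raise ValueError("frame count does not match the schedule")
    if not mask.data.any():
        raise ValueError("empty mask")
    values = dyn[mask.data, :].mean(axis=0)
    return TimeActivityCurve(schedule.mid_min, values)
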