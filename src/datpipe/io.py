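"""NIfTI, timing-sidecar and report I/O."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .schedule import FrameSchedule
from .voi import DEFAULT_LABELS, LabelVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_label_volume",
    "load_label_volume",
    "save_schedule_csv",
    "load_schedule_csv",
    "write_json",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(data: np.ndarray, voxel_size_mm: float, path: str | Path) -> Path:
    path = Path(path)
    dtype = np.int16 if np.issubdtype(data.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("anisotropic voxels are not supported")
    return np.asarray(img.dataobj), float(zooms[0])


def save_label_volume(labels: LabelVolume, path: str | Path) -> Path:
    """Write the label image plus a JSON sidecar with the label dictionary."""
    path = Path(path)
    save_nifti(labels.data.astype(np.int16), labels.voxel_size_mm, path)
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    sidecar.write_text(json.dumps(labels.labels, indent=1))
    return path


def load_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    data, vox = load_nifti(path)
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    if sidecar.exists():
        label_map = json.loads(sidecar.read_text())
    else:
        label_map = dict(DEFAULT_LABELS)
    return LabelVolume(data.astype(np.int16), vox, labels=label_map)


def save_schedule_csv(schedule: FrameSchedule, path: str | Path) -> Path:
    path = Path(path)
    schedule.to_frame().to_csv(path, index=False)
    return path


def load_schedule_csv(path: str | Path) -> FrameSchedule:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame-timing sidecar not found: {path}")
    return FrameSchedule.from_frame(pd.read_csv(path))


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=_default))
    return path
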