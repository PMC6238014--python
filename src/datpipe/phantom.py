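"""Voxelized dynamic PET and static SPECT phantoms with known ground truth.

Regions are ellipsoids on an isotropic grid.  The default voxel size,
1.4626 mm, makes a 2.5 mL fixed-volume selection exactly 799 voxels.  Each
region is filled with its SRTM time-activity curve (dynamic phantom) or a
constant background*(1 + SUR) level (SPECT phantom), smoothed per frame by a
Gaussian point-spread function (3.2 mm FWHM PET-like, 12.5 mm SPECT-like),
with optional zero-mean Gaussian noise whose variance is proportional to
activity divided by frame duration.

The special region "background" models non-specific brain uptake: it is
filled first and carries low binding, so PSF smoothing produces realistic
spill-in/spill-out at region borders.  All other regions must not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .kinetics import (
    GammaVariateInput,
    KineticParameters,
    DEFAULT_REFERENCE_MODEL,
    TimeActivityCurve,
    fine_grid,
    frame_average,
    simulate_reference_tac,
    srtm_continuous,
)
from .schedule import FrameSchedule, make_default_schedule
from .voi import DEFAULT_LABELS, LabelVolume

__all__ = [
    "RegionGeometry",
    "PhantomSpec",
    "default_phantom_spec",
    "build_label_volume",
    "build_dynamic_phantom",
    "build_spect_phantom",
    "DEFAULT_VOXEL_MM",
]

#: chosen so a 2.5 mL top-k selection is exactly 799 voxels
DEFAULT_VOXEL_MM = (2500.0 / 799.0) ** (1.0 / 3.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RegionGeometry:
    """Axis-aligned ellipsoid: centre and semi-axes in mm, grid-centre origin."""

    center_mm: tuple
    semi_axes_mm: tuple

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or len(self.semi_axes_mm) != 3:
            raise ValueError("centre and semi-axes must be 3-vectors")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics, resolution and noise settings for one phantom."""

    voxel_size_mm: float = DEFAULT_VOXEL_MM
    grid_shape: tuple = (64, 64, 48)
    regions: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    psf_fwhm_mm: float = 3.2
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.psf_fwhm_mm < 0 or self.noise_scale < 0:
            raise ValueError("psf_fwhm and noise_scale must be non-negative")

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


#: HC-like default binding potentials per region; non-specific tissue sits
#: near the reference level, as a valid reference region presumes
_DEFAULT_BP = {
    "background": 0.1,
    "occipital": 0.1,
    "cerebellum": 0.0,
    "caudate_L": 2.9,
    "caudate_R": 2.9,
    "putamen_L": 3.8,
    "putamen_R": 3.8,
    "SN_L": 0.7,
    "SN_R": 0.7,
}

#: midbrain/striatum separation keeps the SN search box clear of smoothed
#: putamen spill-over
_DEFAULT_GEOMETRY = {
    "background": RegionGeometry((0.0, 0.0, -1.0), (44.0, 44.0, 33.0)),
    "caudate_L": RegionGeometry((-12.0, 22.0, 8.0), (7.5, 11.0, 8.5)),
    "caudate_R": RegionGeometry((12.0, 22.0, 8.0), (7.5, 11.0, 8.5)),
    "putamen_L": RegionGeometry((-25.0, 6.0, 4.0), (9.0, 13.0, 8.0)),
    "putamen_R": RegionGeometry((25.0, 6.0, 4.0), (9.0, 13.0, 8.0)),
    "cerebellum": RegionGeometry((0.0, -27.0, -25.0), (30.0, 13.0, 8.5)),
    "SN_L": RegionGeometry((-9.0, -12.0, -14.0), (4.0, 5.5, 3.5)),
    "SN_R": RegionGeometry((9.0, -12.0, -14.0), (4.0, 5.5, 3.5)),
    "occipital": RegionGeometry((0.0, -34.0, 4.0), (17.0, 7.0, 11.0)),
}


def default_phantom_spec(
    bp_overrides: dict | None = None,
    r1: float = 0.9,
    k2: float = 0.5,
    **spec_kw,
) -> PhantomSpec:
    """Default brain-like phantom; bp_overrides replaces per-region true BP_ND."""
    bps = dict(_DEFAULT_BP)
    if bp_overrides:
        bps.update(bp_overrides)
    kin = {
        name: KineticParameters(1.0 if name == "cerebellum" else r1, k2, bp)
        for name, bp in bps.items()
    }
    return PhantomSpec(regions=dict(_DEFAULT_GEOMETRY), kinetics=kin, **spec_kw)


def _voxel_coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    return [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size_mm
        for n in spec.grid_shape
    ]


def _ellipsoid_mask(spec: PhantomSpec, geom: RegionGeometry) -> np.ndarray:
    cx, cy, cz = geom.center_mm
    ax, ay, az = geom.semi_axes_mm
    x, y, z = _voxel_coords_mm(spec)
    half = [c[-1] + spec.voxel_size_mm / 2.0 for c in (x, y, z)]
    for c, a, h in zip(geom.center_mm, geom.semi_axes_mm, half):
        if abs(c) + a > h:
            raise ValueError("region extends outside the grid")
    xx = ((x - cx) / ax) ** 2
    yy = ((y - cy) / ay) ** 2
    zz = ((z - cz) / az) ** 2
    return (
        xx[:, None, None] + yy[None, :, None] + zz[None, None, :]
    ) <= 1.0


def build_label_volume(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the region geometries into an integer label volume.

    "background" is rasterized first; all other regions must be pairwise
    non-overlapping on the voxel grid.
    """
    labels = {
        name: DEFAULT_LABELS.get(name, max(DEFAULT_LABELS.values()) + 1 + i)
        for i, name in enumerate(spec.regions)
    }
    data = np.zeros(spec.grid_shape, dtype=np.int16)
    claimed = np.zeros(spec.grid_shape, dtype=bool)
    ordered = sorted(spec.regions, key=lambda n: n != "background")
    for name in ordered:
        m = _ellipsoid_mask(spec, spec.regions[name])
        if name != "background":
            if np.any(claimed & m):
                raise ValueError(f"region {name!r} overlaps another region")
            claimed |= m
        data[m] = labels[name]
    return LabelVolume(data, spec.voxel_size_mm, labels=labels)


def _smooth(volume: np.ndarray, fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    if fwhm_mm == 0:
        return volume
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    return ndimage.gaussian_filter(volume, sigma_vox)


def build_dynamic_phantom(
    spec: PhantomSpec,
    model: GammaVariateInput = DEFAULT_REFERENCE_MODEL,
    schedule: FrameSchedule | None = None,
) -> tuple[np.ndarray, LabelVolume, dict]:
    """4-D dynamic phantom with per-region SRTM TACs.

    Returns (image, labels, truth) where truth maps region name to a dict
    with the generating TAC and the true BP_ND.  Noise is zero-mean Gaussian
    with variance noise_scale**2 * activity / frame duration (minutes),
    drawn from the spec seed.
    """
    schedule = schedule or make_default_schedule()
    labels = build_label_volume(spec)
    tgrid = fine_grid(schedule)
    truth: dict = {}
    region_tacs: dict[str, TimeActivityCurve] = {}
    for name in spec.regions:
        params = spec.kinetics[name]
        tac = frame_average(tgrid, srtm_continuous(model, params, tgrid), schedule)
        region_tacs[name] = tac
        truth[name] = {"tac": tac, "bp_nd_true": params.bp_nd_true}
    truth["__reference__"] = {"tac": simulate_reference_tac(model, schedule)}

    img = np.zeros(spec.grid_shape + (schedule.n_frames,), dtype=np.float32)
    masks = {name: labels.data == labels.labels[name] for name in spec.regions}
    for f in range(schedule.n_frames):
        frame = np.zeros(spec.grid_shape, dtype=np.float64)
        # background first, specific regions override inside it
        for name in sorted(spec.regions, key=lambda n: n != "background"):
            frame[masks[name]] = region_tacs[name].values[f]
        frame = _smooth(frame, spec.psf_fwhm_mm, spec.voxel_size_mm)
        img[..., f] = frame
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        dur_min = schedule.durations_min
        sd = spec.noise_scale * np.sqrt(
            np.clip(img, 0.0, None) / dur_min[None, None, None, :]
        )
        img = (img + rng.normal(0.0, 1.0, img.shape) * sd).astype(np.float32)
    return img, labels, truth


def build_spect_phantom(
    spec: PhantomSpec,
    region_sur: dict,
    background_level: float = 10.0,
    psf_fwhm_mm: float = 12.5,
) -> tuple[np.ndarray, LabelVolume, dict]:
    """3-D SPECT-like phantom: region intensity = background*(1 + SUR).

    region_sur maps region name -> true specific uptake ratio (>= -1).
    Regions absent from the map get SUR 0 (background level).  Requires a
    "background" region in the spec; ground-truth SURs are returned.
    """
    if "background" not in spec.regions:
        raise ValueError("SPECT phantom requires a 'background' region")
    if any(s < -1 for s in region_sur.values()):
        raise ValueError("SUR values must be >= -1")
    unknown = set(region_sur) - set(spec.regions)
    if unknown:
        raise KeyError(f"SUR given for unknown regions: {sorted(unknown)}")
    labels = build_label_volume(spec)
    img = np.zeros(spec.grid_shape, dtype=np.float64)
    for name in sorted(spec.regions, key=lambda n: n != "background"):
        m = labels.data == labels.labels[name]
        img[m] = background_level * (1.0 + region_sur.get(name, 0.0))
    img = _smooth(img, psf_fwhm_mm, spec.voxel_size_mm)
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_scale * np.sqrt(np.clip(img, 0.0, None))
        img = img + rng.normal(0.0, 1.0, img.shape) * sd
    truth = {name: {"sur_true": region_sur.get(name, 0.0)} for name in spec.regions}
    return img, labels, truth
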