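import numpy as np
import pytest

import datpipe as dp


@pytest.fixture(scope="session")
def schedule():
    return dp.make_default_schedule()


@pytest.fixture(scope="session")
def ref_model():
    return dp.DEFAULT_REFERENCE_MODEL


@pytest.fixture(scope="session")
def ref_tac(ref_model, schedule):
    return dp.simulate_reference_tac(ref_model, schedule)


@pytest.fixture(scope="session")
def phantom_sharp(schedule):
    """Noiseless, unsmoothed phantom: voxel values equal region TACs exactly."""
    spec = dp.default_phantom_spec(psf_fwhm_mm=0.0)
    dyn, labels, truth = dp.build_dynamic_phantom(spec, schedule=schedule)
    return spec, dyn, labels, truth


@pytest.fixture(scope="session")
def phantom_smoothed(schedule):
    """Noiseless phantom at PET-like 3.2 mm FWHM resolution."""
    spec = dp.default_phantom_spec(psf_fwhm_mm=3.2)
    dyn, labels, truth = dp.build_dynamic_phantom(spec, schedule=schedule)
    return spec, dyn, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def compact_spec(**kw):
    """Small, fast phantom: 32x32x24 grid at 2 mm with shrunken regions."""
    from datpipe.phantom import PhantomSpec, RegionGeometry
    from datpipe.kinetics import KineticParameters

    regions = {
        "background": RegionGeometry((0.0, 0.0, 0.0), (28.0, 28.0, 20.0)),
        "caudate_L": RegionGeometry((-8.0, 18.0, 4.0), (5.0, 6.0, 5.0)),
        "caudate_R": RegionGeometry((8.0, 18.0, 4.0), (5.0, 6.0, 5.0)),
        "putamen_L": RegionGeometry((-18.0, 6.0, 0.0), (6.0, 8.0, 5.0)),
        "putamen_R": RegionGeometry((18.0, 6.0, 0.0), (6.0, 8.0, 5.0)),
        "cerebellum": RegionGeometry((0.0, -16.0, -12.0), (16.0, 8.0, 6.0)),
        "occipital": RegionGeometry((0.0, -22.0, 4.0), (11.0, 5.0, 8.0)),
    }
    bps = {
        "background": 0.1, "occipital": 0.1, "cerebellum": 0.0,
        "caudate_L": 2.9, "caudate_R": 2.9, "putamen_L": 3.8, "putamen_R": 3.8,
    }
    kinetics = {
        name: KineticParameters(1.0 if name == "cerebellum" else 0.9, 0.5, bp)
        for name, bp in bps.items()
    }
    defaults = dict(
        voxel_size_mm=2.0, grid_shape=(32, 32, 24), regions=regions,
        kinetics=kinetics, psf_fwhm_mm=3.2,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)
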