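import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import petmtv as pm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_image():
    """4×4×4 grid of 10 mm voxels (1 cm³ each), SUV 0 everywhere."""
    return pm.SUVImage(np.zeros((4, 4, 4)), spacing=(10, 10, 10))


@pytest.fixture
def two_blob_image():
    """Two avid blobs separated by sub-threshold background."""
    v = np.zeros((7, 5, 5))
    v[0:2, 0:2, 0:2] = 3.0   # blob A
    v[5:7, 3:5, 3:5] = 4.0   # blob B
    v[3, 2, 2] = 1.0         # sub-threshold bridge voxel
    return pm.SUVImage(v, spacing=(10, 10, 10))


@pytest.fixture
def core_rim_phantom():
    """Two-compartment lesion (core SUV 10, rim SUV 3) on a quiet background
    with a cool liver; the canonical method-divergence fixture."""
    lesion = pm.LesionSpec(
        center=(96, 96, 96), semi_axes=(30, 30, 30), core_suv=10.0, rim_suv=3.0,
        core_fraction=0.6,
    )
    spec = pm.PhantomSpec(
        shape=(48, 48, 48),
        spacing=(4, 4, 4),
        background_suv=0.3,
        background_noise_sd=0.05,
        lesions=(lesion,),
        liver_center=(40.0, 40.0, 60.0),
        liver_mean=1.0,
        liver_sd=0.1,
        rng_seed=7,
    )
    return pm.generate_phantom(spec)


@pytest.fixture
def cohort():
    return pm.generate_cohort(pm.CohortSpec(rng_seed=11))
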