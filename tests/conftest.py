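import pytest
from hypothesis import HealthCheck, settings

from trabspec import AnalysisConfig
from trabspec.synthetic_bone import (
    GrfBoneParams,
    PlatePhantomParams,
    generate_grf_bone,
    generate_plate_phantom,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def plate_phantom():
    """Plates 0.2 mm thick repeating every 1 mm: 1D profile is a duty-0.2
    square wave with 5 exact periods over the 5 mm extent."""
    return generate_plate_phantom(
        PlatePhantomParams(
            period_mm=1.0,
            plate_thickness_mm=0.2,
            normal_axis=0,
            volume_shape_vox=(500, 20, 20),
            voxel_size_mm=0.01,
        )
    )


@pytest.fixture(scope="session")
def small_grf():
    """96^3 bone-like volume at 0.02 mm voxels (~1.9 mm extent)."""
    return generate_grf_bone(
        GrfBoneParams(volume_shape_vox=(96, 96, 96), rng_seed=11)
    )


@pytest.fixture(scope="session")
def coarse_grf():
    """125^3 bone-like volume at 0.04 mm voxels: a full (5 mm)^3 VOI at
    desk-test resolution (bands and physical geometry unchanged)."""
    return generate_grf_bone(
        GrfBoneParams(
            volume_shape_vox=(125, 125, 125), voxel_size_mm=0.04, rng_seed=11
        )
    )


@pytest.fixture()
def default_config():
    return AnalysisConfig()
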