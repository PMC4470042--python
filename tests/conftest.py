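import numpy as np
import pytest

from bonetrack.synthetic import SceneSpec, make_rig


@pytest.fixture(scope="session")
def spec():
    return SceneSpec(seed=1)


@pytest.fixture(scope="session")
def rig(spec):
    return make_rig(spec)


@pytest.fixture(scope="session")
def small_spec():
    """Quarter-size detector for cheap rendering in unit tests."""
    return SceneSpec(
        seed=1,
        detector_px=(336, 276),
        pixel_pitch_mm=0.16,
        bone_size_mm=12.0,
        bone_subdivisions=18,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
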