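import numpy as np
import pytest
from hypothesis import settings

from thermasym import PipelineConfig, PhantomSpec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A compact noiseless face phantom for fast geometry tests.

    The vertical axis passes through integer column 50 of a 101-column grid,
    so mirror symmetry is an exact column flip.
    """
    return PhantomSpec(
        shape=(96, 101),
        face_center=(48.0, 50.0),
        face_semiaxes=(36.0, 26.0),
        axis_angle_deg=0.0,
        noise_sd_c=0.0,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
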