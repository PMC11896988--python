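import numpy as np
import pytest

from ivimon.fragsim import SimConfig, TrackerGeometry
from ivimon.phantom import PhantomGeometry
from ivimon.plan import DEFAULT_RANGE_MODEL, ScannerGeometry


@pytest.fixture(scope="session")
def geom() -> PhantomGeometry:
    return PhantomGeometry()


@pytest.fixture(scope="session")
def scanner() -> ScannerGeometry:
    return ScannerGeometry()


@pytest.fixture(scope="session")
def tracker() -> TrackerGeometry:
    return TrackerGeometry()


@pytest.fixture(scope="session")
def range_model():
    return DEFAULT_RANGE_MODEL


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_sim_config() -> SimConfig:
    """The simulator settings of the default study configuration."""
    from ivimon.study import StudyConfig, build_objects
    return build_objects(StudyConfig())[6]
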