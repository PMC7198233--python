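import numpy as np
import pytest

from flyopto.hitdetect import BodyPartition
from flyopto.synthetic_fly import FlyBodyModel, WalkParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def model():
    return FlyBodyModel()


@pytest.fixture(scope="session")
def partition(model):
    return BodyPartition.from_body_model(model)


@pytest.fixture
def straight_walk():
    """Deterministic straight-line walk parameters (no noise, no arena)."""
    return WalkParams(speed_sd_mm_s=0.0, turn_sd_rad_s=0.0, arena_mm=None,
                      start_heading_rad=0.0, start_xy=(0.0, 0.0))
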