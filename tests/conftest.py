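import numpy as np
import pytest

import optoflow as of
from optoflow.core import Episode, IlluminationSchedule


@pytest.fixture(scope="session")
def always_on() -> IlluminationSchedule:
    return IlluminationSchedule([Episode(0.0, 1e6, 1.0)])


@pytest.fixture(scope="session")
def aligned_texture() -> np.ndarray:
    """Default texture: streaks along x with fine speckle, 192 px."""
    return of.gen_texture(seed=3, shape=(192, 192), correlation_length=6.0)


@pytest.fixture(scope="session")
def cycle_schedule() -> IlluminationSchedule:
    """One activation cycle: 60 s dark, 120 s light, then dark again."""
    return IlluminationSchedule([Episode(0.0, 60.0, 0.0), Episode(60.0, 180.0, 1.0),
                                 Episode(180.0, 400.0, 0.0)])
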