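import numpy as np
import pytest

from dropcode.config import RunConfig
from dropcode.mls import MaskBank, default_codes, generate_mls
from dropcode.simulate import ChannelGeometry, ExcitationSchedule


@pytest.fixture(scope="session")
def codes():
    return default_codes()


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def schedule():
    return ExcitationSchedule()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def bank(config):
    """Default 500-velocity mask bank on the default geometry."""
    return config.mask_bank()


@pytest.fixture(scope="session")
def small_bank(codes):
    """A small, fast bank for unit tests: 63-px masks on 300-px traces."""
    c1, c2 = codes
    grid = np.linspace(1.1, 1.6, 41)  # px/ms; exposure 63 ms -> 69-101 px
    return MaskBank(c1, c2, grid, exposure=63.0, trace_length=300,
                    duty1=0.5)
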