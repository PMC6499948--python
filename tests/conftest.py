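import numpy as np
import pytest

from gazecal.geometry import ScreenLayout, default_task_suite


@pytest.fixture(scope="session")
def screen():
    return ScreenLayout()


@pytest.fixture(scope="session")
def suite(screen):
    """The four default task layouts on the default 6.2 x 11.0 cm screen."""
    return default_task_suite(screen)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
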