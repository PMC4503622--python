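import numpy as np
import pytest

from vesishape import GridSpec, OptimizerSettings, build_library


@pytest.fixture(scope="session")
def fast_settings():
    """Low-degree solver settings for unit tests whose physics is not
    resolution-limited (budded-branch competition needs the default)."""
    return OptimizerSettings(max_degree=12)


@pytest.fixture(scope="session")
def tiny_library(fast_settings):
    """Small library spanning sphere-like through budded entries."""
    grid = GridSpec(0.95, 1.35, 0.10, 0.75, 1.00, 0.08)
    return build_library(grid, settings=fast_settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
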