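import numpy as np
import pytest

from caltrack.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small default-noise simulation shared by read-only tests."""

    cfg = SimulationConfig(image_shape=(256, 256), n_frames=200, n_cells=4, seed=11)
    stack, gt, morph = simulate(cfg)
    return cfg, stack, gt, morph


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
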