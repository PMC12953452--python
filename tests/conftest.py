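import warnings

import numpy as np
import pytest

from rowcount import NoiseConfig, SceneConfig, generate

# the simulator's clustering/tracking warnings are expected in bulk runs
warnings.filterwarnings("ignore", message="predicted area non-positive")


@pytest.fixture(scope="session")
def small_scene_noisefree():
    """A short noise-free oblique walk (~60 plants), shared across tests."""
    return generate(SceneConfig(plot_length=3.0), NoiseConfig.none(), seed=11)


@pytest.fixture(scope="session")
def mid_scene_noisefree():
    """Half-length noise-free walk (~140 plants), single clean row."""
    return generate(SceneConfig(plot_length=7.2), NoiseConfig.none(), seed=4)


@pytest.fixture(scope="session")
def small_scene_noisy():
    """The same short walk with the default detector noise model."""
    return generate(SceneConfig(plot_length=3.0), NoiseConfig(), seed=11)


@pytest.fixture(scope="session")
def clutter_scene():
    """Half-length plot flanked by two clutter rows, default noise."""
    return generate(
        SceneConfig(plot_length=7.2, n_side_rows=2), NoiseConfig(), seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
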