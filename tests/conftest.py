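import numpy as np
import pytest

from monkeyhab.synthetic_data import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    cfg = SceneConfig(
        grid_shape=(60, 60), pixel_size=100.0, n_villages=40, n_groups=2, seed=7
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
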