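import numpy as np
import pytest

from forestcondition.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 48x48 synthetic landscape shared by read-only tests."""
    return generate_scene(SceneConfig(grid_shape=(48, 48), seed=11))


@pytest.fixture(scope="session")
def full_crossing_grids():
    """Land cover / region grids in which every (class, region) pair occurs."""
    regions = np.repeat(np.arange(1, 12), 8)[:, None] * np.ones(16, int)
    land_cover = np.ones((88, 1), int) * np.tile(np.arange(1, 5), 4)
    return land_cover.astype(np.int16), regions.astype(np.int16)
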