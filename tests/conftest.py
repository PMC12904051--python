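import numpy as np
import pytest

from corrtaste.datatypes import StimulusSchedule
from corrtaste.synthetic import generate_scene, render_reporter


@pytest.fixture(scope="session")
def small_scene():
    """12-cell bud at study geometry, with nerve ROIs; shared read-only."""
    return generate_scene(
        12, seed=11, image_shape=(192, 192), bud_diameter_um=55.0, n_nerves=8
    )


@pytest.fixture(scope="session")
def small_reporter(small_scene):
    rng = np.random.default_rng(99)
    return render_reporter(small_scene) + rng.normal(0, 0.01, small_scene.shape)


@pytest.fixture()
def short_schedule():
    """Sweet+umami protocol at 1 Hz (20 s saliva, 20 s stim, 50 s washout)."""
    return StimulusSchedule.default(tastants=("sweet", "umami"))
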