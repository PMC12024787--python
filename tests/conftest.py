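import numpy as np
import pytest

from histoblob import make_scene, render_rgb


@pytest.fixture(scope="session")
def small_scene():
    """A modest scene shared by read-only tests."""
    return make_scene(12, (96, 96), 0.25, 0.3, seed=5, n_clutter=2, noise_sd=0.02)


@pytest.fixture(scope="session")
def small_image(small_scene):
    return render_rgb(small_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
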