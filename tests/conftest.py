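import numpy as np
import pytest

import gastro3d as g


@pytest.fixture(scope="session")
def small_scene():
    """A small labeled cavity scene with cameras (shared, read-only)."""
    return g.small_scene(seed=11)


@pytest.fixture(scope="session")
def sphere_cloud():
    """2000 noiseless unit-sphere samples (directions double as true normals)."""
    rng = np.random.default_rng(7)
    d = rng.normal(size=(2000, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
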