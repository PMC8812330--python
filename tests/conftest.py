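import numpy as np
import pytest

from ldcontacts.synthetic import generate_scene, random_scene


@pytest.fixture(scope="session")
def scene_pair():
    """Two independent dense synthetic scenes with ground truth."""
    return generate_scene(random_scene(seed=201)), generate_scene(random_scene(seed=202))


@pytest.fixture(scope="session")
def scene():
    """One dense synthetic scene (stack, truth)."""
    return generate_scene(random_scene(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_histogram(rng, n_modes=2):
    """A plausible 256-bin image histogram: mixture of Gaussian modes + floor."""
    counts = np.zeros(256)
    for _ in range(n_modes):
        mu = rng.uniform(10, 245)
        sd = rng.uniform(3, 30)
        n = int(rng.integers(200, 5000))
        vals = np.clip(rng.normal(mu, sd, n).round().astype(int), 0, 255)
        counts += np.bincount(vals, minlength=256)
    counts += rng.integers(0, 3, 256)
    return counts
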