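import numpy as np
import pytest

from nitroxkit import synthdata


@pytest.fixture(scope="session")
def table4():
    return synthdata.load_fixture("table4")


@pytest.fixture(scope="session")
def table4_frame():
    return synthdata.load_fixture_frame("table4")


@pytest.fixture(scope="session")
def table6():
    return synthdata.load_fixture("table6")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_isometry(rng):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=5.0, size=3)
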