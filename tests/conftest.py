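import numpy as np
import pytest
from hypothesis import settings

from hectorvi import LungMask, ScalarVolume, VentilationMap, default_spec, generate_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_case():
    """A 32-cube noise-free phantom shared by cheap structural tests."""
    return generate_phantom(default_spec(dims=32, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_hu_volume(rng):
    vals = rng.uniform(-1000.0, 100.0, (16, 16, 16))
    return ScalarVolume(vals, spacing=(1.0, 1.2, 2.5), origin=(-3.0, 4.0, 9.5), unit="hu")


def make_map(values, mask_values, phase="exhale"):
    mask = LungMask(np.asarray(mask_values, bool), phase=phase)
    return VentilationMap(np.asarray(values, float), mask=mask), mask


@pytest.fixture()
def box_mask():
    m = np.zeros((12, 12, 12), bool)
    m[2:10, 2:10, 2:10] = True
    return LungMask(m, phase="exhale")
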