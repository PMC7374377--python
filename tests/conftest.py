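import numpy as np
import pytest

from saliencyfcm.synthetic import NoiseSpec, corrupt, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_region_phantom():
    return make_phantom("two_region", 96, 96, levels=(60, 180))


@pytest.fixture
def four_region_phantom():
    return make_phantom("four_region", 128, 128, levels=(40, 100, 160, 220))


@pytest.fixture
def noisy_two_region(two_region_phantom):
    spec = NoiseSpec("gaussian", gaussian_std=10.0, seed=7)
    return corrupt(two_region_phantom.clean, spec), two_region_phantom
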