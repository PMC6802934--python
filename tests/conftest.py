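import numpy as np
import pytest

from bilayergate.geometry import align_to_pore_axis
from bilayergate.synthetic import synthetic_kcsa_tetramer


@pytest.fixture(scope="session")
def tetramer():
    """Synthetic closed-state pore-domain Cα tetramer (constructed geometry)."""
    return synthetic_kcsa_tetramer()


@pytest.fixture(scope="session")
def aligned_tetramer(tetramer):
    return align_to_pore_axis(tetramer)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
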