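import numpy as np
import pytest

from petindex import PhantomSpec, VoxelGrid, generate_phantom


def make_grid(values, spacing=(1.0, 1.0, 1.0), tag="binary"):
    return VoxelGrid(np.asarray(values), spacing, (0, 0, 0), tag)


def empty_grid(shape, spacing=(1.0, 1.0, 1.0), tag="binary"):
    return VoxelGrid(np.zeros(shape, dtype=np.int32), spacing, (0, 0, 0), tag)


@pytest.fixture(scope="session")
def phantom_case():
    """One default lesion-bearing phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(PhantomSpec(seed=11, noise_sigma_suv=0.0))
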