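import numpy as np
import pytest

from dwisr.phantoms import PhantomSpec, make_dwi_phantom, make_shepp_logan


@pytest.fixture(scope="session")
def shepp64():
    return make_shepp_logan(PhantomSpec(matrix_size=64))


@pytest.fixture(scope="session")
def dwi8():
    """8-direction anisotropic tensor phantom, 64^2."""
    return make_dwi_phantom(PhantomSpec(name="dwi_tensor", matrix_size=64,
                                        n_directions=8, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
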