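import numpy as np
import pytest

from dicosar import SMatrix, SynthArraySpec, VOPSet, synth_smatrix, synth_vops


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_hermitian(rng, n, psd=True):
    A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    if psd:
        return A @ A.conj().T / n
    return 0.5 * (A + A.conj().T)


@pytest.fixture
def small_instance():
    """A 3-channel, 4-VOP instance with a moderately coupled array."""
    vops = synth_vops(3, 4, 3, seed=7)
    S = synth_smatrix(SynthArraySpec(3, diag_reflection=0.4, coupling_scale=0.3, seed=8))
    return S, vops


@pytest.fixture
def identity_vop():
    return VOPSet(np.eye(2)[None, :, :])


@pytest.fixture
def zero_smatrix():
    return SMatrix(np.zeros((3, 3)))
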