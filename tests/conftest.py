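import numpy as np
import pytest

import isqsm


@pytest.fixture(scope="session")
def phantom64():
    """Default synthetic phantom: 64³, seed 0, field SNR 100."""
    return isqsm.make_default_phantom(size=64, seed=0, snr=100.0)


@pytest.fixture(scope="session")
def kernel64(phantom64):
    return isqsm.dipole_kernel(phantom64.chi_truth.grid)


@pytest.fixture(scope="session")
def is_recon64(phantom64, kernel64):
    """IS reconstruction of the default phantom at t_well = 0.25, defaults."""
    return isqsm.is_reconstruct(
        phantom64.field, phantom64.mask, kernel64, isqsm.SolverConfig(t_well=0.25)
    )


@pytest.fixture(scope="session")
def tkd_recon64(phantom64, kernel64):
    """PSF-corrected TKD reconstruction at the theoretical-optimum δ = 2/3."""
    return isqsm.tkd_reconstruct(
        phantom64.field, kernel64, isqsm.TKDConfig(delta=2.0 / 3.0, psf_correct=True)
    )


@pytest.fixture
def grid8():
    return isqsm.VolumeGrid((8, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
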