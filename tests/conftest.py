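import numpy as np
import pytest

from hemekin import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_mcd():
    """Noiseless two-state decay series with its ground truth."""
    return syn.gen_two_state_mcd_series(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def true_basis(noiseless_mcd):
    from hemekin.mcd import BasisSet

    _, truth = noiseless_mcd
    return BasisSet(
        basis_complex=truth.basis_complex,
        basis_free=truth.basis_free,
        zero_cross_nm=552.5,
        f0=1.0,
        asymmetry_score=0.0,
    )


@pytest.fixture(scope="session")
def gaussian_ensemble():
    """Small isotropic-fluctuation ensemble (sigma 0.5 A)."""
    return syn.gen_ensemble(n_residues=20, n_frames=500, sigma_A=0.5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
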