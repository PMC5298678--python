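import numpy as np
import pytest

from tpmp import Dictionary, make_dct_basis, synthesize_sparse_ecg


@pytest.fixture(scope="session")
def dct8():
    return make_dct_basis(8)


@pytest.fixture(scope="session")
def small_dictionary():
    """6x12 Bernoulli/DCT dictionary, the workhorse tiny instance."""
    return Dictionary.bernoulli_dct(6, 12, seed=7)


@pytest.fixture(scope="session")
def ortho_matrix():
    """A square orthonormal dictionary matrix (correlations decouple)."""
    return make_dct_basis(12).entries


def make_instance(n, m, k, seed, snr_db=None, bias=False):
    """One seeded (dictionary, sparse, y, sigma2) recovery instance."""
    D = Dictionary.bernoulli_dct(m, n, seed=seed)
    _, sparse = synthesize_sparse_ecg(n, k, seed=seed + 10_000, low_freq_bias=bias)
    clean = D.product @ sparse.coefficients
    if snr_db is None:
        return D, sparse, clean, 0.0
    sigma2 = float(clean @ clean) * 10 ** (-snr_db / 10) / m
    rng = np.random.default_rng(seed + 20_000)
    return D, sparse, clean + rng.normal(0, np.sqrt(sigma2), m), sigma2
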