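import numpy as np
import pytest

from hequery.simd_backend import derive_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_params():
    """Factory for small validated-shape parameter sets.

    t = 65537 is prime and satisfies 2n | t - 1 for every n <= 32768, so a
    single modulus serves all test ring sizes.
    """

    def make(n=32, t=65537, d=3, b=4, ell=12, N_prime=None):
        return derive_params(n=n, t=t, d=d, b=b, ell=ell, N_prime=N_prime)

    return make
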