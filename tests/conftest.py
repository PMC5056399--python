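import numpy as np
import pytest

from mutatorqs import MutatorParams, make_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20160840)


@pytest.fixture
def linear_k03():
    return make_landscape("linear", k=0.3)


@pytest.fixture
def quadratic_c3():
    return make_landscape("quadratic", c=3.0)


@pytest.fixture
def table4_params():
    """The four uni-directional linear-fitness parameter columns."""
    return [
        (MutatorParams(L=1000, mu1=1.0, mu2=10.0, alpha1=a), k)
        for k, a in ((0.3, 0.0001), (0.3, 0.001), (0.3, 0.01), (1.0, 0.3))
    ]


def random_symmetric_setup(rng, L=None):
    """A random tabulated landscape plus random positive rates."""
    if L is None:
        L = int(rng.integers(2, 9))
    values = rng.uniform(0.0, 2.0, L + 1)
    land = make_landscape("tabulated", values=values)
    params = MutatorParams(
        L=L,
        mu1=float(rng.uniform(0.1, 2.0)),
        mu2=float(rng.uniform(0.1, 4.0)),
        alpha1=float(rng.uniform(0.05, 1.0)),
        alpha2=float(rng.uniform(0.05, 1.0)),
    )
    return params, land
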