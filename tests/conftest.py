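import numpy as np
import pytest

from kinecrit import (
    make_branched_compensation,
    make_central_carbon,
    make_linear_chain,
    make_normal_form_oscillator,
)


@pytest.fixture(scope="session")
def ccm():
    """The bundled synthetic central-carbon-style model."""
    return make_central_carbon()


@pytest.fixture
def chain2():
    """2-metabolite chain: inflow 1, k = (2, 4); steady state (0.5, 0.25)."""
    return make_linear_chain(2, v0=1.0, k=[2.0, 4.0])


@pytest.fixture
def chain3():
    return make_linear_chain(3, v0=1.0, k=[1.0, 2.0, 4.0])


@pytest.fixture
def branched():
    return make_branched_compensation()


@pytest.fixture
def oscillator():
    """Normal form, beta=-1, sigma=+1, 2 contracting + 1 expanding dims."""
    return make_normal_form_oscillator(-1.0, +1, n_stable=2, n_unstable=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
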