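import numpy as np
import pytest

from oarseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default-sized phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def symmetric_phantom():
    """A phantom with jitter disabled: exact lateral symmetry."""
    return generate_phantom(PhantomSpec(seed=7).symmetric())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
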