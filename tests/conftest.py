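import numpy as np
import pytest

from tiltkit.scheme import generate_grouped_dose_symmetric, load_builtin_scheme


@pytest.fixture(scope="session")
def pm36():
    return load_builtin_scheme("pm36")


@pytest.fixture(scope="session")
def pm60():
    return load_builtin_scheme("pm60")


@pytest.fixture(scope="session")
def small_scheme():
    """A short +-12 deg scheme for fast closed-loop tests."""
    return generate_grouped_dose_symmetric(12, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
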