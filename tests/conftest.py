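import numpy as np
import pytest

from streammodes.synthetic import MixtureSpec, generate


@pytest.fixture(scope="session")
def default_mixture() -> MixtureSpec:
    return MixtureSpec()


@pytest.fixture(scope="session")
def default_table():
    """The default two-season, 14-variable synthetic fixture (seed 1)."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def default_mixture_sample(default_mixture):
    """n = 32,196 i.i.d. draws from the default mixture (seed 1)."""
    return default_mixture.sample(32_196, np.random.default_rng(1))
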