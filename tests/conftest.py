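import numpy as np
import pandas as pd
import pytest

from mendriver.simulate import generate_planted_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def planted():
    """Default-scale planted-module study: 200 background features,
    one 10-member disease module, 100 samples."""
    return generate_planted_fixture(seed=1)


@pytest.fixture(scope="session")
def small_planted():
    """Reduced planted study for the slower MMI route."""
    return generate_planted_fixture(
        n_background=60, module_sizes=[10], n_samples=80, seed=3
    )


@pytest.fixture
def toy_profile():
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.lognormal(size=(6, 12)),
        index=[f"f{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(12)],
    )
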