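import numpy as np
import pytest

from mvds.cohort import default_config, generate_cohort
from mvds.scale import load_scale_definition


@pytest.fixture(scope="session")
def scale():
    return load_scale_definition()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n=56) on a fixed seed."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
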