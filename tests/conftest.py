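import numpy as np
import pytest
from hypothesis import settings

from endosym.simulate import blochmannia_tree

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_tree():
    return blochmannia_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
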