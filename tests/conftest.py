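import numpy as np
import pytest

from scoredfu.synth import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 mixed-severity synthetic scenes shared across read-only tests."""
    return generate_dataset(60, (0.25, 0.25, 0.25, 0.25), seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
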