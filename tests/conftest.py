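import numpy as np
import pytest

from epfassay.datasets import load_screening_reference
from epfassay.synthetic import SyntheticConfig, generate_truth


@pytest.fixture(scope="session")
def screening_reference():
    return load_screening_reference()


@pytest.fixture(scope="session")
def small_truth():
    cfg = SyntheticConfig(seed=42, n_isolates=4)
    return generate_truth(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
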