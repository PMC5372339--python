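import numpy as np
import pandas as pd
import pytest

from cocapipe.integration import ClassificationLayer
from cocapipe.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20170329)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced default cohort shared by integration-level tests."""
    return generate_cohort(default_cohort_spec(seed=7, n_samples=150))


def make_layer(name, mapping):
    """ClassificationLayer from a {sample: label} dict (None = missing)."""
    s = pd.Series(mapping, dtype=object)
    return ClassificationLayer(name, s)
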