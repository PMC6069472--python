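import numpy as np
import pytest

from painface import synthetic


@pytest.fixture(scope="session")
def template():
    return synthetic.neutral_template()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three subjects, four epochs, rendered frames; shared across IO/pipeline tests."""
    spec = synthetic.CohortSpec(n_subjects=3, epochs_per_subject=4, frames_per_epoch=12, seed=11)
    return synthetic.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
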