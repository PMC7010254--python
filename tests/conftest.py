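import numpy as np
import pytest

from cogfactor import synthetic as syn


@pytest.fixture(scope="session")
def latent_spec():
    return syn.default_behavioral_spec(n_subjects=114, seed=0)


@pytest.fixture(scope="session")
def behav_data(latent_spec):
    return syn.generate_behavioral(latent_spec)


@pytest.fixture(scope="session")
def template_spec():
    return syn.default_template_spec(seed=0)


@pytest.fixture(scope="session")
def task_maps(template_spec):
    return syn.generate_task_maps(template_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
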