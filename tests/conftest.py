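import numpy as np
import pytest

from bmimed.cohort import prepare_cohort
from bmimed.pipeline import RunConfig, build_designs
from bmimed.simulate import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def gen_params():
    return GeneratorParams(n=1500, seed=77)


@pytest.fixture(scope="session")
def cohort(gen_params):
    """A prepared mid-size synthetic cohort shared across tests."""
    data, log = prepare_cohort(generate_cohort(gen_params))
    return data


@pytest.fixture(scope="session")
def grimage_designs(cohort, gen_params):
    cfg = RunConfig(generator=gen_params)
    m_des, o_des, _ = build_designs(cohort, "grimage", cfg)
    return m_des, o_des


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
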