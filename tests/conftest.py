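import numpy as np
import pytest
from hypothesis import settings

from repsample.prep import EligibilityRules
from repsample.report import run_pipeline
from repsample.sampler import SamplerConfig
from repsample.synthetic import PopulationConfig, generate_population

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_population():
    """A 2,000-per-cancer registry draw shared across unit tests."""
    cfg = PopulationConfig.default(n_per_cancer=2000, seed=11)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def full_run():
    """Full pipeline on a 100,000-row population (the validation-study scale)."""
    cfg = PopulationConfig.default(n_per_cancer=25_000, seed=1)
    art = run_pipeline(cfg, SamplerConfig(seed=1), EligibilityRules())
    return art


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
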