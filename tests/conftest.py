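import numpy as np
import pytest

from polywasp.model_core import (
    SimulationConfig,
    SurvivalDistributions,
    default_template,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    """Default strategy template (every sex-choice probability 0.5)."""
    return default_template()


@pytest.fixture
def exact_template():
    """Template with deterministic (sd = 0) survival, for hand-countable runs."""
    survival = SurvivalDistributions(
        male_single_sex=(32.4, 0.0),
        female_single_sex=(45.7, 0.0),
        male_in_related_mixed=(32.4, 0.0),
        female_in_related_mixed=(45.7, 0.0),
        male_in_unrelated_mixed=(20.0, 0.0),
        female_in_unrelated_mixed=(40.0, 0.0),
    )
    return default_template(survival=survival)


@pytest.fixture
def small_config():
    return SimulationConfig(host_count=40, generations=10,
                            host_acceptance_threshold=0.55, rng_seed=7)
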