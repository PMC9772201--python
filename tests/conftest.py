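import numpy as np
import pytest

import memchoice as mc
from memchoice import inference, screening


@pytest.fixture(scope="session")
def default_config():
    return mc.CohortConfig(seed=3)


@pytest.fixture(scope="session")
def bank(default_config):
    return mc.make_item_bank(default_config)


@pytest.fixture(scope="session")
def power_template(default_config):
    return inference.default_power_template(default_config, seed=3)


@pytest.fixture(scope="session")
def choice_trials(bank, power_template, default_config):
    """A 44-participant study-scale choice cohort (logistic backend)."""
    rng = np.random.default_rng(7)
    return mc.cohort.simulate_choice_cohort(
        bank, power_template.z_mem, 44, default_config.choice_params, rng
    )


@pytest.fixture(scope="session")
def kept_choice_trials(choice_trials):
    report = screening.screen(choice_trials)
    return screening.kept_trials(choice_trials, report)


@pytest.fixture(scope="session")
def small_choice_trials(bank, power_template, default_config):
    """A reduced 20-participant cohort for expensive (MCMC) tests."""
    rng = np.random.default_rng(11)
    return mc.cohort.simulate_choice_cohort(
        bank, power_template.z_mem, 20, default_config.choice_params, rng
    )
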