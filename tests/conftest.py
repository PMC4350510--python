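import numpy as np
import pytest

from rewardbias.task import ScheduleConfig, generate_schedule


@pytest.fixture(scope="session")
def default_schedule():
    """One default-design schedule (3 x 100 trials) with a fixed seed."""
    return generate_schedule(ScheduleConfig(rng_seed=12345))


@pytest.fixture()
def rng():
    return np.random.default_rng(999)
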