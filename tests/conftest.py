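import numpy as np
import pytest

import betaburst as bb


@pytest.fixture(scope="session")
def one_run_schedule():
    return bb.make_nback_schedule(1, seed=42)


@pytest.fixture(scope="session")
def schedule_with_behavior(one_run_schedule):
    resp = bb.simulate_behavior(one_run_schedule, hit_rate=0.95, seed=43)
    return one_run_schedule.with_responses(resp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
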