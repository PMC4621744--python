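import numpy as np
import pytest

import fearephys as fp


@pytest.fixture(scope="session")
def default_schedule() -> fp.EventSchedule:
    return fp.generate_schedule(seed=0)


@pytest.fixture(scope="session")
def three_day_schedules() -> list[fp.EventSchedule]:
    return [fp.generate_schedule(seed=100 + d, day=d) for d in (1, 2, 3)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
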