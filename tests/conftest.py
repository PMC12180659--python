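import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_snapshot(times, loads_by_time, condition="test"):
    """Build a snapshot DataFrame from {time: [loads]}."""
    records = []
    for t in times:
        for i, load in enumerate(loads_by_time[t]):
            records.append((f"w{t}_{i}", float(t), float(load), condition))
    return pd.DataFrame(records, columns=["worm_id", "time_h", "load", "condition"])


@pytest.fixture
def snapshot_factory():
    return make_snapshot
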