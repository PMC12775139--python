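import numpy as np
import pytest
from hypothesis import settings

# derandomised hypothesis runs: same examples in every environment
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_record():
    """Small 3-channel, 2 s, 250 Hz record with one event."""
    from frustmi import SignalRecord

    gen = np.random.default_rng(0)
    data = gen.normal(0, 10, size=(3, 500))
    return SignalRecord(
        data=data,
        rate=250.0,
        channel_names=["C3", "C4", "Oz"],
        events=[(100, "MI/left")],
    )
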