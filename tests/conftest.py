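from datetime import datetime, timedelta

import pytest

from raetrace.event_io import default_registry
from raetrace.features import WindowChunk
from raetrace.synthetic_data import default_aruba_model, generate_days


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def model():
    return default_aruba_model()


@pytest.fixture(scope="session")
def three_day_log(model):
    return generate_days(model, 3, seed=11)


@pytest.fixture(scope="session")
def ten_day_log(model):
    return generate_days(model, 10, seed=12)


@pytest.fixture
def worked_example_chunk(registry):
    """The printed one-minute sequence M7,M3,M7,M3,M5,M4."""
    tokens = [registry.index(s) for s in ("M7", "M3", "M7", "M3", "M5", "M4")]
    start = datetime(2021, 1, 1, 8, 0)
    return WindowChunk(start=start, end=start + timedelta(minutes=1),
                       tokens=tokens, event_indices=list(range(6)))
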