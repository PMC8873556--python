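import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from tapclust import TapEvent, TapSession

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_session_path() -> Path:
    return DATA / "worked_session.jsonl"


@pytest.fixture(scope="session")
def worked_session_expected() -> dict:
    return json.loads((DATA / "worked_session_expected.json").read_text())


def make_session(t, x, y, pid="S", recorded_at=0.0) -> TapSession:
    events = [TapEvent(float(a), float(b), float(c)) for a, b, c in zip(t, x, y)]
    return TapSession.from_events(pid, recorded_at, events)


def random_session(seed: int, n: int = 30) -> TapSession:
    """Session with alternating two-target geometry and generic jitter."""
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(0.2, 0.8, size=n))
    side = np.arange(n) % 2
    x = np.where(side == 0, 150.0, 330.0) + rng.normal(0, 15, size=n)
    y = 400.0 + rng.normal(0, 12, size=n)
    return make_session(t, x, y)


@pytest.fixture
def random_session_factory():
    return random_session
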