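from pathlib import Path

import numpy as np
import pytest

from salsup import ExGaussParams, ObserverConfig, make_schedule, simulate_session

DATA_DIR = Path(__file__).parent / "data"

BASELINE = ExGaussParams(K=1.2, loc=640.0, scale=72.0)
CAPTURE = ExGaussParams(K=1.0, loc=850.0, scale=90.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fixture_csv() -> Path:
    return DATA_DIR / "search_fixture_200.csv"


@pytest.fixture(scope="session")
def fixture_ledger() -> Path:
    return DATA_DIR / "search_fixture_200_ledger.json"


@pytest.fixture(scope="session")
def small_session():
    """One deterministic simulated session (study-condition observer)."""
    schedule = make_schedule(seed=11)
    observer = ObserverConfig(seed=11)
    return simulate_session(observer, schedule, participant="p001")
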