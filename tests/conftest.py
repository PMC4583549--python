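"""Shared fixtures: seeded generators and small simulated datasets."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from betasort import (
    BetasortParams,
    QParams,
    make_monkey_schedule,
    run_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def betasort_monkey_record():
    """One simulated betasort monkey-protocol session with snapshots."""
    rng = np.random.default_rng(42)
    schedule = make_monkey_schedule(rng)
    return run_session(
        "betasort", BetasortParams(tau=0.05, xi=0.95), schedule, rng, snapshot=True
    )


@pytest.fixture(scope="session")
def qsoftmax_monkey_record():
    """One simulated Q/softmax monkey-protocol session with snapshots."""
    rng = np.random.default_rng(43)
    schedule = make_monkey_schedule(rng)
    return run_session(
        "qsoftmax", QParams(alpha=0.03, beta=10.0), schedule, rng, snapshot=True
    )


@pytest.fixture(scope="session")
def betasort_monkey_records():
    """Twenty independent betasort monkey-protocol sessions."""
    params = BetasortParams(tau=0.05, xi=0.95)
    records = []
    for stream in np.random.SeedSequence(7).spawn(20):
        rng = np.random.default_rng(stream)
        records.append(run_session("betasort", params, make_monkey_schedule(rng), rng))
    return records
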