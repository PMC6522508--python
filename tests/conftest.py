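import numpy as np
import pytest

from meldalloc import default_config, simulate_cohort
from meldalloc.registry import compute_meld, derive_outcome


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized calibrated cohort shared across tests (deterministic)."""
    config = default_config(n=3000, seed=11)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def cohort_arrays(default_cohort):
    _, records = default_cohort
    meld = np.array([compute_meld(r.labs).score for r in records])
    outcomes = [derive_outcome(r) for r in records]
    time = np.array([o.time_days for o in outcomes])
    event = np.array([o.event for o in outcomes])
    hcc = np.array([r.hcc for r in records])
    return meld, time, event, hcc
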