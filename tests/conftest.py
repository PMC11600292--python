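import numpy as np
import pandas as pd
import pytest

from circmm.simcohort import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def whole_bm_cohort():
    """Small whole bone-marrow cohort shared across tests."""
    return simulate_cohort(CohortDesign(n_mm=14, n_hc=6, mode="whole_bm", seed=101))


@pytest.fixture(scope="session")
def purified_cohort():
    """Small purified plasma-cell cohort shared across tests."""
    return simulate_cohort(CohortDesign(n_mm=20, mode="purified_pc", seed=102))


def random_survival(rng: np.random.Generator, n: int, event_frac: float = 0.8):
    """Exponential survival times with uniform censoring for test instances."""
    t_event = rng.exponential(30.0, size=n)
    censor = rng.uniform(5.0, 120.0, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    return np.maximum(time, 1e-3), event
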