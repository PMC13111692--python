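import numpy as np
import pandas as pd
import pytest

from riskrank import synthetic_cohort, task_model
from riskrank.pt_model import PTParams


@pytest.fixture(scope="session")
def battery():
    """The full default pair battery (both domains, all three conditions)."""
    return task_model.generate_battery(seed=1)


@pytest.fixture(scope="session")
def typical_params():
    """A behaviourally typical agent: risk-averse in gains, risk-seeking in
    losses, loss-averse, mild S-shaped gain weighting."""
    return PTParams(
        rho_plus=0.2, rho_minus=-0.5, lam=3.0,
        alpha_plus=1.2, alpha_minus=0.65, mu=5.0, x0=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused across tests (8 animals, 2 chunks)."""
    cfg = synthetic_cohort.CohortConfig(
        n_individuals=8, n_males=5, months=8, trials_per_individual=3000, seed=11
    )
    return synthetic_cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def events_5():
    """Hand-checkable 5-event displacement log over three individuals."""
    days = pd.to_datetime(
        ["2020-03-01", "2020-03-02", "2020-03-03", "2020-03-04", "2020-03-05"]
    )
    return pd.DataFrame(
        {
            "timestamp": days,
            "winner_id": ["a", "a", "c", "b", "c"],
            "loser_id": ["b", "c", "b", "a", "a"],
        }
    )
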