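import numpy as np
import pandas as pd
import pytest

from ionsig.cohort import ExpressionCohort
from ionsig.simulate import SimulationConfig, simulate_cohort


def make_cohort(values, genes, samples, clinical=None, cohort_id="TEST", presence=None):
    """Assemble an ExpressionCohort from raw pieces, filling clinical gaps."""
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    base = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for col in ("p53_status", "er_status", "pr_status", "node_status", "size_class"):
        base[col] = pd.array([None] * len(samples), dtype="string")
    for col in ("grade", "age_years", "time", "event"):
        base[col] = np.nan
    if clinical:
        for col, vec in clinical.items():
            base[col] = vec
    pres = None
    if presence is not None:
        pres = pd.DataFrame(np.asarray(presence, dtype=bool), index=genes, columns=samples)
    return ExpressionCohort(cohort_id=cohort_id, values=vals, clinical=base, presence=pres)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=123), "SIM")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
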