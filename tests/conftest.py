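import pandas as pd
import pytest

from statintol.config import RulesConfig, SimulationConfig
from statintol.phenotyping import classify_cohort
from statintol.simulate import simulate_observational_cohort


@pytest.fixture(scope="session")
def rules():
    return RulesConfig()


@pytest.fixture(scope="session")
def small_bundle(rules):
    """A modest synthetic cohort shared across tests (seeded, deterministic)."""
    cfg = SimulationConfig(n_patients=1500, seed=11)
    return simulate_observational_cohort(cfg, rules)


@pytest.fixture(scope="session")
def small_assignments(small_bundle, rules):
    return classify_cohort(
        small_bundle.prescriptions,
        small_bundle.labs,
        small_bundle.patients,
        rules,
        small_bundle.records_end,
    )


def scripts(rows):
    """Build a prescriptions frame from (pid, drug, dose, start, days) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "drug", "daily_dose_mg", "start_date", "days_supply"]
    )


def labs_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "analyte", "value"])
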