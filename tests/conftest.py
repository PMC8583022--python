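import numpy as np
import pandas as pd
import pytest

from dietscore.outcomes import CONDITIONS
from dietscore.simulate import (
    SimulationConfig,
    generate_cohort,
    make_worked_profiles,
    sodium_reference_profiles,
)


@pytest.fixture(scope="session")
def profiles():
    return make_worked_profiles()


@pytest.fixture(scope="session")
def sodium_ref_sample():
    return sodium_reference_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(n_participants=1500, seed=42))


def null_simulation_config(n: int, seed: int) -> SimulationConfig:
    """A cohort with no diet-outcome association at all (no diet effects,
    no confounding paths)."""
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        diet_effects={c: 0.0 for c in CONDITIONS},
        ses_effect=0.0,
        smoking_effect=0.0,
        death_diet_effect=0.0,
    )


def toy_reports(rows):
    """Build a condition-report frame from (pid, wave, condition) triples."""
    return pd.DataFrame(
        [{"participant_id": p, "wave": w, "condition": c, "reported": 1} for p, w, c in rows],
        columns=["participant_id", "wave", "condition", "reported"],
    )
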