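import dataclasses

import numpy as np
import pytest

from prefiv import (
    ExclusionRules,
    InstrumentSpec,
    SimulationConfig,
    apply_exclusions,
    attach_outcome,
    build_instrument,
    generate_population,
    select_index_prescriptions,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_physicians=60,
        patients_per_physician=50,
        preference_sd=1.5,
        baseline_risk=0.2,
        treatment_effect=-10.0,
        confounder_effect_rx=0.0,
        confounder_effect_y=0.0,
        linked_fraction=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def cohort_z1(population):
    """Cohort with Z1 built, from the small confounder-free population."""
    prescriptions, patients, outcomes, truth = population
    candidates, _ = select_index_prescriptions(prescriptions, patients)
    cohort, log = apply_exclusions(candidates, patients, prescriptions, ExclusionRules())
    cohort, _ = attach_outcome(cohort, outcomes)
    cohort, _ = build_instrument(cohort, prescriptions, InstrumentSpec(1, "most_recent"))
    return cohort


def replace(config, **kw):
    return dataclasses.replace(config, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
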