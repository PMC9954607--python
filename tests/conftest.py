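import pytest

from pepscreen import RunConfig, SimulationConfig, run_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (seed 1)."""
    config = RunConfig(simulation=SimulationConfig(seed=1), seed=1)
    return run_pipeline(config)


SMALL_CONFIG = SimulationConfig(
    n_cases=60,
    n_controls=60,
    n_cases_validation=40,
    n_controls_validation=40,
    n_cases_validation2=20,
    n_features=400,
    n_markers=60,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit-level checks."""
    return simulate_cohort(SMALL_CONFIG)
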