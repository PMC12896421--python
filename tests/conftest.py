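import pytest

from albigrid import GridSpec, SyntheticCohortConfig, generate_cohort, run_simulation


@pytest.fixture(scope="session")
def default_summary():
    """Annotated 0.1-step CP-A grid simulation."""
    return run_simulation()


@pytest.fixture(scope="session")
def coarse_summary():
    """0.2-step sensitivity grid."""
    return run_simulation(GridSpec(step=0.2))


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-patient synthetic cohort with ground truth."""
    cfg = SyntheticCohortConfig(n_patients=2000, seed=11)
    records, truth = generate_cohort(cfg)
    return cfg, records, truth
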