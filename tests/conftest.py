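import numpy as np
import pytest

from airbrain import (
    SimulationConfig,
    apply_exclusions,
    simulate_cohort,
    summarize_cohort,
)

ZERO_EFFECTS = {
    k: (0.0, 0.0, 0.0)
    for k in (
        "icv",
        "white_matter",
        "cortical_gm",
        "ventricles",
        "cerebellum",
        "deep_grey",
        "brainstem",
        "amygdala_hippocampus",
        "extracerebral_csf",
    )
}


@pytest.fixture(scope="session")
def default_cohort():
    """One full enrolled cohort under the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_summary(default_cohort):
    """Post-exclusion analysis table of the default cohort."""
    filtered, _ = apply_exclusions(default_cohort)
    return summarize_cohort(filtered)


@pytest.fixture(scope="session")
def planted_summary():
    """Analysis table of a cohort carrying a planted rho=0.5 canonical mode."""
    cohort = simulate_cohort(SimulationConfig(seed=42, planted_rho=0.5))
    filtered, _ = apply_exclusions(cohort)
    return summarize_cohort(filtered)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
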