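import numpy as np
import pytest

from cnvlnc import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default nine-patient synthetic study with ten planted drivers."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with no dosage effect and hazard ratio 1 (global null)."""
    return simulate_cohort(
        SimulationConfig(seed=1, dosage_effect=0.0, survival_hr=1.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240930)
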