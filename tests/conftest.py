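import numpy as np
import pytest

from coretransim import SimulationConfig, run_sweep
from coretransim.experiments import standard_fit_table

#: root seed for the shared reduced-scale sweep, fixed once for the suite
SWEEP_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def reduced_sweep():
    """Reduced-scale study sweep: 10 replicates x 5 h_A x 10 detection levels.

    Session-scoped because it takes a few minutes; all statistical acceptance
    checks share it.
    """
    return run_sweep(reps=10, root_seed=SWEEP_SEED)


@pytest.fixture(scope="session")
def sweep_fits(reduced_sweep):
    return standard_fit_table(reduced_sweep.rows)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast configuration for engine and orchestration tests."""
    return SimulationConfig(
        width=8, height=8, h_a=0.5, n_species=8, carrying_capacity=20,
        n_steps=25, occupancy_window=5, seed=0,
    )
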