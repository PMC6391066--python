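import numpy as np
import pytest

from v1gamma.synth import ConditionSpec, SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact two-condition session reused across pipeline-level tests."""
    cfg = SimulationConfig(
        conditions=[
            ConditionSpec(
                "chromatic", gamma_amplitude=3.0, locking_kappa=1.0,
                rate_sustained=12.0, line_amplitudes=(0.3, 0.1, 0.05),
            ),
            ConditionSpec(
                "achromatic", gamma_amplitude=0.4, locking_kappa=0.1,
                rate_sustained=30.0, line_amplitudes=(0.3, 0.1, 0.05),
            ),
        ],
        n_trials_per_condition=8,
        grid_shape=(1, 2),
        seed=7,
    )
    return simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
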