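import numpy as np
import pytest

from fepkit import (CoupledHamiltonian, PotentialSpec, SamplerConfig,
                    make_lambda_schedule, metropolis_sample)


@pytest.fixture(scope="session")
def harmonic_1to4():
    """1-D harmonic k: 1 -> 4 kcal/(mol*A^2), shared center."""
    return CoupledHamiltonian(
        endpoint_A=PotentialSpec("harmonic", {"k": 1.0, "center": 0.0}),
        endpoint_B=PotentialSpec("harmonic", {"k": 4.0, "center": 0.0}))


@pytest.fixture(scope="session")
def harmonic_replicas_small(harmonic_1to4):
    """Cheap MC fixture: 11 windows x 2000 steps x 5 replicas."""
    cfg = SamplerConfig(n_steps_per_window=2000, n_replicas=5, seed=11)
    return metropolis_sample(harmonic_1to4, make_lambda_schedule(11), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
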