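import numpy as np
import pytest

import seedmem as sm

# Default study conditions: Y0=0, Y1=4, V=0.9; good runs geometric(mean 5),
# bad runs discretised N(5,2) truncated to [0,10]; p = 0.5, q* = 0.354839.
P_GOOD = 0.5
Q_STAR = (P_GOOD * 4.0 - 0.9) / (4.0 - 0.9)


@pytest.fixture(scope="session")
def fitness() -> sm.FitnessMatrix:
    return sm.FitnessMatrix()


@pytest.fixture(scope="session")
def structured_model() -> sm.EnvironmentModel:
    return sm.default_structured_model()


@pytest.fixture(scope="session")
def env_train(structured_model) -> sm.EnvironmentSequence:
    """Training sequence for optimisation (common random numbers)."""
    return sm.generate_environment(structured_model, 201_000, rng=11, burn_in=1000)


@pytest.fixture(scope="session")
def env_eval(structured_model) -> sm.EnvironmentSequence:
    """Held-out sequence, independent seed."""
    return sm.generate_environment(structured_model, 201_000, rng=12, burn_in=1000)


@pytest.fixture(scope="session")
def env_long(structured_model) -> sm.EnvironmentSequence:
    """Million-year sequence for lineage and information statistics."""
    return sm.generate_environment(structured_model, 1_000_000, rng=31, burn_in=1000)
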