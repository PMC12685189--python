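import numpy as np
import pytest

from biofilmchemostat.model import (ParameterSet, SystemState, STABLE_MEDIANS,
                                    REFERENCE_INITIAL, MEDIAN_ALPHA, MEDIAN_X3_INIT)
from biofilmchemostat.simulate import SolverSettings


@pytest.fixture(scope="session")
def medians() -> ParameterSet:
    """Reference stable-median parameter set (biofilm adhesion enabled)."""
    return STABLE_MEDIANS


@pytest.fixture(scope="session")
def initial_no_cheater() -> SystemState:
    return REFERENCE_INITIAL


@pytest.fixture(scope="session")
def initial_with_cheater() -> SystemState:
    return SystemState(S=REFERENCE_INITIAL.S, E1=REFERENCE_INITIAL.E1, E2=0.0,
                       X1=REFERENCE_INITIAL.X1, X2=0.0, X3=MEDIAN_X3_INIT)


@pytest.fixture(scope="session")
def short_settings() -> SolverSettings:
    """Reduced horizon for tests that only need transient behaviour."""
    return SolverSettings(t_end=2000.0)


def random_valid_params(rng: np.random.Generator) -> ParameterSet:
    """A random parameter set drawn from the survey ranges (biofilm on)."""
    lu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    S0 = lu(0.01, 2.0)
    return ParameterSet(
        S0=S0, delta=lu(0.01, 2.0), eta=lu(0.01, 2.0), gamma=lu(0.01, 2.0),
        E2_max=lu(0.01, 2.0), X2_max=lu(0.01, 2.0),
        beta_E=lu(0.001, 1.0), beta_X=lu(0.001, 1.0), alpha=lu(0.001, 1.0),
        D=float(rng.uniform(0.1, 1.0)), Q=float(rng.uniform(0.1, 1.0)),
        mu=float(rng.uniform(1.0, 100.0)), K_S=lu(0.001, S0)).validate()


def random_state(rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 2.0, size=6)
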