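import numpy as np
import pytest

from phenoswitch import (
    InitialComposition,
    RateParameters,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def drug_params():
    """Canonical drug-phase rates (births suppressed)."""
    return RateParameters(k_E=0.0, k_M=0.0, mu_E=0.3, mu_M=0.15, k_EM=0.1, k_ME=0.1)


@pytest.fixture(scope="session")
def growth_params():
    """Canonical growth-phase rates of the simulation study."""
    return RateParameters(k_E=0.2, k_M=0.1, mu_E=0.3, mu_M=0.15, k_EM=0.1, k_ME=0.1)


def random_rate_grid(n, seed, lo=0.0, hi=2.0):
    """Random valid parameter sets, uniform over [lo, hi]^6."""
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=(n, 6))
    return [RateParameters(*row) for row in draws]


@pytest.fixture(scope="session")
def drug_ensemble_fixed_p0(drug_params):
    """Shared drug-phase ensemble with a fixed mixed initial fraction."""
    init = InitialComposition(N0=200, p0=0.2, mode="binomial")
    grid = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
    return simulate_ensemble(drug_params, init, grid, 10_000, seed=101)


@pytest.fixture(scope="session")
def growth_ensemble(growth_params):
    """Shared growth-phase ensemble from 200 sensitive cells."""
    init = InitialComposition(N0=200, p0=0.0, mode="deterministic")
    grid = np.array([0.0, 0.1, 1.0, 10.0, 20.0])
    return simulate_ensemble(growth_params, init, grid, 10_000, seed=202)
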