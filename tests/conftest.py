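import numpy as np
import pytest

from fgba import ParameterSet


@pytest.fixture(scope="session")
def partial():
    """Partially timescale-separated reference parameter set."""
    return ParameterSet(beta_G=50.0, beta_F=10.0, q=30.0, gamma=10.0,
                        phi_G=1.0, phi_A=1.0, mu=0.01, f0=0.01, g0=0.01,
                        f1=0.5, g1=1.0)


@pytest.fixture(scope="session")
def separated():
    """Fully timescale-separated reference parameter set."""
    return ParameterSet(beta_G=5e4, beta_F=1e4, q=2e4, gamma=500.0,
                        phi_G=1.0, phi_A=1.0, mu=0.01, f0=0.01, g0=0.01,
                        f1=0.05, g1=0.1)


def draw_random_params(rng, n):
    """Log-uniform draws over the plausible rate ranges (grass/fire block)."""
    out = []
    for _ in range(n):
        g0 = 10.0 ** rng.uniform(-3, -1)
        f0 = 10.0 ** rng.uniform(-3, -1)
        out.append(ParameterSet(
            beta_G=10.0 ** rng.uniform(1, 5),
            beta_F=10.0 ** rng.uniform(0, 4),
            q=10.0 ** rng.uniform(1, 5),
            gamma=10.0 ** rng.uniform(0, 3),
            phi_G=10.0 ** rng.uniform(-1, 1),
            phi_A=10.0 ** rng.uniform(-1, 1),
            mu=10.0 ** rng.uniform(-3, -1),
            f0=f0, f1=f0 + 10.0 ** rng.uniform(-2, 0),
            g0=g0, g1=g0 + 10.0 ** rng.uniform(-2, 0)))
    return out
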