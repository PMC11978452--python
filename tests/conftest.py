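import math

import numpy as np
import pytest

from spatburst import Domain1D, ModelParams


@pytest.fixture
def base_params() -> ModelParams:
    """Baseline kinetics used across the moment and distribution tests."""
    return ModelParams(lam=10.0, alpha=1.0, beta=1.0, gamma=1.0, D=1.0, z=0.3, kappa=math.inf)


@pytest.fixture
def absorbing_domain() -> Domain1D:
    return Domain1D(R=1.0, boundary="absorbing")


@pytest.fixture
def robin_domain() -> Domain1D:
    return Domain1D(R=1.0, boundary="robin")


@pytest.fixture
def param_hypercube() -> list[dict]:
    """Ten scrambled parameter sets spanning the sweep ranges, used for
    oracle-equivalence checks of the closed forms."""
    rng = np.random.default_rng(12345)
    sets = []
    for _ in range(10):
        R = rng.uniform(0.6, 1.5)
        sets.append(
            dict(
                lam=rng.uniform(2.0, 25.0),
                alpha=rng.uniform(0.3, 3.0),
                beta=rng.uniform(0.3, 3.0),
                gamma=rng.uniform(0.3, 3.0),
                D=rng.uniform(0.3, 3.0),
                z=rng.uniform(-0.8, 0.8) * R,
                R=R,
                kappa=rng.uniform(0.3, 20.0),
            )
        )
    return sets
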