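import numpy as np
import pytest

from crisprdyn import (
    SimulationConfig,
    SingleSpacerParams,
    SingleState,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture
def reference_params():
    """Single-spacer coexistence regime: effective spacer, slow spacer loss."""
    return SingleSpacerParams(
        f0=1.0, r=1.0, K=1e5, kappa=2e-3, g=1e-5, eta=0.005, alpha=1e-4, mu=1.0, b=100.0
    )


@pytest.fixture
def naive_culture():
    """Small all-wild-type culture hit by a large phage inoculum."""
    return SingleState(n0=1000.0, n1=0.0, I0=0.0, I1=0.0, v=1e4)


@pytest.fixture
def fast_config():
    return SimulationConfig(t_max=500.0, n_outputs=400)


def random_single_params(rng) -> SingleSpacerParams:
    return SingleSpacerParams(
        f0=rng.uniform(0.5, 2.0),
        r=rng.uniform(0.5, 1.5),
        K=rng.uniform(1e4, 1e6),
        kappa=rng.uniform(0.0, 0.05),
        g=10 ** rng.uniform(-6, -4),
        eta=rng.uniform(0.0, 1.0),
        alpha=rng.uniform(0.0, 0.5),
        mu=rng.uniform(0.2, 3.0),
        b=rng.uniform(1.0, 300.0),
        dilution=rng.choice([0.0, rng.uniform(0.0, 1e-2)]),
        phage_decay=rng.choice([0.0, rng.uniform(0.0, 1e-2)]),
    )


def random_single_state(rng, K: float) -> SingleState:
    return SingleState(*rng.uniform(0.0, K, size=4), v=rng.uniform(0.0, 100 * K))
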