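import numpy as np
import pytest

from cohesim import experiments, simulate_ensemble


@pytest.fixture(scope="session")
def short_kv_ensemble():
    """Small KV ensemble reused by structural tests (30 reps, 600 steps)."""
    cfg = experiments.make_config(
        model="kv", amplitude=1.0, period=5, n_steps=600, seed=123
    )
    return simulate_ensemble(cfg, 30)


@pytest.fixture(scope="session")
def short_sls_ensemble():
    """Small SLS ensemble reused by structural tests."""
    cfg = experiments.make_config(
        model="sls", amplitude=1.0, period=5, n_steps=600, seed=123
    )
    return simulate_ensemble(cfg, 30)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
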