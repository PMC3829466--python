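import numpy as np
import pytest

from cghbench.types import ProbeSeries, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20130217)


@pytest.fixture
def step_series():
    """Noiseless two-segment series: 0 on [0, 50), 1.0 on [50, 100)."""
    v = np.zeros(100)
    v[50:] = 1.0
    return ProbeSeries(values=v, label="step")


def make_profile(N=2000, snr=3.0, noise_family="gaussian", seed=0, rep=0, **kw):
    from cghbench.synthetic_data import simulate_profile

    cfg = SimulationConfig(N=N, snr=snr, noise_family=noise_family, seed=seed, **kw)
    return simulate_profile(cfg, rep)
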