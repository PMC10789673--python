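import numpy as np
import pytest
from hypothesis import settings

import lordq as lq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def default_eff():
    return lq.EfficiencyPair(e_long=1.82, e_short=1.98)


@pytest.fixture
def single_control():
    return lq.ControlSet([
        lq.SampleCtSummary("ctrl", "control", ct_long_mean=20.0, ct_short_mean=15.0)
    ])


@pytest.fixture
def noiseless_plate():
    """A tiny noiseless simulated experiment (control + one dose)."""
    cfg = lq.SimConfig(
        lambda_per_bp={"control": 0.0, "uv": 6e-4},
        ct_noise_sd=0.0,
        cells_per_group=3,
        seed=7,
    )
    return lq.simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
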