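import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """A small simulated dataset shared by training/CLI tests."""
    from deepcac.synthetic_data import SimConfig, make_default_pwms, simulate_to_dataset

    pwms = make_default_pwms(3, m=6, sharpness=8.0, seed=11)
    cfg = SimConfig(n=120, length=40, pwms=tuple(pwms), prevalence=0.4, seed=11)
    return simulate_to_dataset(cfg)
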