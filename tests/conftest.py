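import numpy as np
import pytest

from saaidkit import NoiseModel, SyntheticTruth, TwoChannelStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A 4-depth random stack with strictly positive intensities."""
    shape = (4, 16, 16)
    return TwoChannelStack(
        shg=rng.uniform(1, 100, shape),
        af=rng.uniform(1, 100, shape),
        depths_um=np.arange(4) * 4.0,
        meta={"animal": "m1", "group": "control", "day": 7},
    )


@pytest.fixture
def noiseless_truth():
    """Day-7-shaped truth with noise disabled (exact inverse identity)."""
    return SyntheticTruth(
        target_saaid_profile=((0.0, 40.0, 80.0), (0.0, -0.4, 0.2)),
        noise=NoiseModel(enabled=False),
        seed=7,
    )
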