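import numpy as np
import pytest

from emgaug import FixtureConfig, MultichannelSignal, generate_fixture


@pytest.fixture(scope="session")
def small_dataset():
    """3 gestures x 5 repetitions, 4 channels, 1 s at 100 Hz."""
    cfg = FixtureConfig(
        n_gestures=3, n_channels=4, n_repetitions=5, duration_s=1.0, rng_seed=11
    )
    return generate_fixture(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noise_signal(rng):
    """A 2-channel white-noise record, 500 samples at 100 Hz."""
    return MultichannelSignal(rng.standard_normal((500, 2)), 100.0)
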