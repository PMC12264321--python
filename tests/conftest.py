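import numpy as np
import pytest

from ramandose import (MicroscopeConfig, PreprocessConfig, default_phantom,
                       instrument_preset, make_axis)


@pytest.fixture(scope="session")
def film():
    """Default-parameter phantom large enough for a 100x100 um^2 ROI."""
    return default_phantom(seed=11)


@pytest.fixture(scope="session")
def cfg_noisy():
    return instrument_preset("custom-60x")


@pytest.fixture(scope="session")
def cfg_clean():
    """Noise-free 60x preset (shot noise off, no cosmic rays)."""
    return instrument_preset("custom-60x", shot_noise=False)


@pytest.fixture(scope="session")
def preprocess_cfg(cfg_noisy):
    return PreprocessConfig(response=cfg_noisy.response)


@pytest.fixture()
def bare_config():
    """Minimal instrument: identity response, no baseline, no noise."""
    return MicroscopeConfig(axis=make_axis(614.0, 2313.0, 2.0),
                            shot_noise=False, baseline_amplitude=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
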