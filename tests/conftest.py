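"""Shared fixtures: small phantoms and simulated force volumes.

Session-scoped where the object is read-only, so the expensive simulations
run once.  All randomness is seeded; nothing here touches the network or
any file outside pytest's tmp paths.
"""

import numpy as np
import pytest

from prestressmap import (AcquisitionConfig, ModelConfig, TipDescriptors,
                          make_phantom, simulate_spectrum_image)

NOISE_RMS = 0.03e-9  # 1% of the 3 nN mapping trigger


@pytest.fixture(scope="session")
def phantom16():
    return make_phantom(nx=16, ny=16, seed=0)


@pytest.fixture(scope="session")
def clean16(phantom16):
    """Noiseless 16x16 force volume + ground truth."""
    return simulate_spectrum_image(phantom16, AcquisitionConfig(noise_rms=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy16(phantom16):
    """16x16 volume with 1%-of-trigger force noise."""
    return simulate_spectrum_image(
        phantom16, AcquisitionConfig(noise_rms=NOISE_RMS, seed=0))


@pytest.fixture(scope="session")
def hs_cfg():
    return ModelConfig("hs")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def all_model_cfgs():
    return [ModelConfig("hs"), ModelConfig("hertz"), ModelConfig("sneddon"),
            ModelConfig("cslc", r_cell=8e-6)]


@pytest.fixture
def default_inits():
    return {"hs": TipDescriptors(65e-9), "hertz": TipDescriptors(65e-9),
            "sneddon": TipDescriptors(0.35), "cslc": TipDescriptors(65e-9)}
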