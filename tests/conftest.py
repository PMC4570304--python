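import numpy as np
import pytest

import lcmcs


@pytest.fixture(scope="session")
def tiny_data():
    """12-sample, 64-band synthetic dataset (seed fixed)."""
    spectra, targets, sites, gt = lcmcs.generate(lcmcs.TINY_CONFIG, seed=0)
    return spectra, targets, sites, gt


@pytest.fixture(scope="session")
def study_data():
    """Full 280-sample, 2151-band, three-site dataset (seed fixed)."""
    spectra, targets, sites, gt = lcmcs.generate(lcmcs.SyntheticConfig(seed=0))
    return spectra, targets, sites, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
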