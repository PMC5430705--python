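import numpy as np
import pytest

from redoxpipe import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noisefree_redox():
    """Small OxICAT simulation without noise or dropout."""
    cfg = synth.RedoxSimConfig(n_sites=30, noise_cv=0.0, dropout_prob=0.0, seed=11)
    features, truth = synth.gen_redox_features(cfg)
    return cfg, features, truth


@pytest.fixture(scope="session")
def noisy_redox():
    """The study-scale simulation: 1000 sites, CV 0.2, 3 replicates."""
    cfg = synth.RedoxSimConfig(n_sites=1000, noise_cv=0.2, n_replicates=3, seed=5)
    features, truth = synth.gen_redox_features(cfg)
    return cfg, features, truth
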