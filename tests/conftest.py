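import numpy as np
import pytest

from mininfer import (AbundanceProfile, CommunityModelConfig, GAConfig,
                      GLVParameters, generate_dataset, reconstruct_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_otu_profile():
    """T=20 profile of a 2-OTU system with one known interaction."""
    truth = GLVParameters(A=np.array([[0.0, 0.6], [0.0, 0.0]]),
                          r=np.array([0.3, 0.1]))
    profile = reconstruct_profile(np.array([0.5, 0.5]), truth, T=20)
    return profile, truth


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated 5-OTU community, short horizon, for fast inference tests."""
    cfg = CommunityModelConfig(n=5)
    rng = np.random.default_rng(777)
    profile, truth = generate_dataset(cfg, T=30, rng=rng)
    return profile, truth, cfg


@pytest.fixture
def tiny_ga_config():
    """Small-budget GA settings for functional (not benchmark) tests."""
    return GAConfig(population_size=20, generations=15, restarts=2, seed=11,
                    early_stop_window=50,
                    model_prior=CommunityModelConfig(n=5))
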