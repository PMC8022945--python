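import numpy as np
import pytest

import zapforest as z


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 lines x 2 environments, 25 markers, ~40% zeros."""
    markers = z.simulate_markers(30, 25, seed=7)
    effects = z.EffectConfig(
        n_informative_theta=3,
        n_informative_mu=3,
        effect_size_theta=1.5,
        effect_size_mu=0.4,
        intercept_mu=0.8,
        target_zero_fraction=0.4,
        seed=8,
    )
    dataset, truth = z.simulate_zap_phenotypes(markers, ["Env1", "Env2"], effects)
    return dataset, truth
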