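import numpy as np
import pytest

import sonoskill as sk


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator configuration used across the suite."""
    return sk.SyntheticScanConfig(
        n_operators=4,
        clips_per_operator=2,
        duration_range=(6.0, 8.0),
        image_shape=(56, 72),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sk.generate_dataset(small_config)


@pytest.fixture(scope="session")
def embedder():
    return sk.FeatureEmbedder(embed_dim=128, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
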