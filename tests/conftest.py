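import numpy as np
import pytest

from lipocomplex import (ComplexationPipeline, SyntheticSpec, VAETrainConfig,
                         apply_minmax, fit_minmax, generate, train_vae)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic formulation dataset: 272 train (179/93), 69 test."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def normalized_splits(default_dataset):
    params = fit_minmax(default_dataset.train)
    return (params,
            apply_minmax(params, default_dataset.train),
            apply_minmax(params, default_dataset.test))


@pytest.fixture(scope="session")
def trained_vae(normalized_splits):
    """VAE trained at the default schedule on the normalized train split."""
    _, norm_train, _ = normalized_splits
    return train_vae(norm_train, config=VAETrainConfig(seed=3))


@pytest.fixture(scope="session")
def fitted_pipeline(default_dataset):
    pipe = ComplexationPipeline(random_state=0)
    pipe.fit(default_dataset.train.features, default_dataset.train.labels)
    return pipe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
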