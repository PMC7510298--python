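"""Shared fixtures: a classifier trained on the calibrated synthetic dataset
and a Monte-Carlo null at test scale. Session-scoped because training and
null construction are the expensive steps."""

import numpy as np
import pytest

import sig70scan as s
from sig70scan.neuralmodel import NetworkConfig


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Full-scale calibrated synthetic dataset (170 positives, 16,000
    background sites)."""
    return s.synthesize_dataset(s.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def trained_model(synthetic_dataset):
    net = s.build_network(NetworkConfig(seed=11))
    return s.train(net, synthetic_dataset)


@pytest.fixture(scope="session")
def null_distribution(trained_model):
    """Uniform-base null at N=1e5 (p resolution 1e-5)."""
    return s.build_null(trained_model, sample_size=100_000, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_twelve_mer(rng, probs=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), p=probs, size=12))
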