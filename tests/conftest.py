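"""Shared fixtures: the synthetic benchmark and CPU-scale model configs.

Heavy objects (the generated benchmark, the trained teacher) are session-
scoped so the several tests that need a fitted model share one fit.
"""

import numpy as np
import pytest

from pepfun.simulate import default_fixture_spec, sample_dataset
from pepfun.network import NetworkConfig
from pepfun.training import PeptideClassifier, TrainConfig


def small_net_config(**overrides) -> NetworkConfig:
    """Fixture-scale architecture: same blocks as the full model, smaller widths."""
    kw = dict(label_dim=6, embed_dim=32, n_heads=4, filters_per_kernel=16,
              dropout=0.0, dtype="float32")
    kw.update(overrides)
    return NetworkConfig(**kw)


@pytest.fixture(scope="session")
def fixture_spec():
    return default_fixture_spec()


@pytest.fixture(scope="session")
def fixture_records(fixture_spec):
    return sample_dataset(fixture_spec)


@pytest.fixture(scope="session")
def fixture_split(fixture_records):
    """80/20 split of the synthetic benchmark."""
    n_train = int(0.8 * len(fixture_records))
    return fixture_records[:n_train], fixture_records[n_train:]


@pytest.fixture(scope="session")
def net_config():
    return small_net_config()


@pytest.fixture(scope="session")
def trained_teacher(fixture_split, fixture_spec, net_config):
    """Classifier fitted with the focal dice loss, 30 epochs, seed 1."""
    train, _ = fixture_split
    return PeptideClassifier(train, fixture_spec.label_space, net_config).fit(
        TrainConfig(epochs=30, batch_size=64, seed=1, early_stop_patience=None))


@pytest.fixture()
def tiny_records(fixture_records):
    """A 200-record slice for fast optimization smoke tests."""
    return fixture_records[:200]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
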