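"""Shared fixtures: one default synthetic study and one trained regressor per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from neurotap import (
    GeneratorConfig,
    TrainConfig,
    default_system,
    extract_features,
    generate_dataset,
    split_by_subject,
    train_ffbp,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BENCHMARK_SEED = 42


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def default_dataset(generator_config):
    """(records, labels, truth) of the default 20-subject study."""
    return generate_dataset(generator_config)


@pytest.fixture(scope="session")
def feature_rows(default_dataset):
    records, labels, _ = default_dataset
    return extract_features(records, tfc=labels)


@pytest.fixture(scope="session")
def benchmark_split(feature_rows):
    return split_by_subject(feature_rows, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def trained_net(benchmark_split):
    """The benchmark regressor (trained once; reused across tests)."""
    return train_ffbp(benchmark_split, TrainConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def fls():
    return default_system()
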