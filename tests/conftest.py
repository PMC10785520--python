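"""Shared fixtures: one small and one full-size synthetic dataset.

The full fixture (default config, seed 1) and the models trained on it are
session-scoped because several evaluation tests reuse them; the small config
keeps unit tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipr import (
    DnnConfig,
    FeatureSchema,
    SimConfig,
    build_feature_matrix,
    simulate_dataset,
    split_random,
    train,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=200_000,
        n_peaks_per_chrom=20,
        reads_per_chrom=5_000,
        n_interactions=300,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def full_dataset():
    """The default study-condition fixture: 5,000 interactions, seed 1."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def full_features(full_dataset):
    """Full- and minimal-schema design matrices plus the PET-count target."""
    ds = full_dataset
    x_full, y = build_feature_matrix(
        ds.interactions, ds.tracks, ds.genome, ds.motifs, FeatureSchema("full")
    )
    x_min, _ = build_feature_matrix(
        ds.interactions, ds.tracks, ds.genome, ds.motifs, FeatureSchema("minimal")
    )
    return x_full, x_min, y


@pytest.fixture(scope="session")
def split_75_25(full_features):
    x_full, _, _ = full_features
    return split_random(list(range(len(x_full))), 0.75, seed=1)


@pytest.fixture(scope="session")
def trained_models(full_features, split_75_25):
    """rf, gb and dnn fitted on the 75% training split of the full fixture."""
    x_full, x_min, y = full_features
    tr, _ = split_75_25
    xt = x_full.iloc[tr].reset_index(drop=True)
    xt_min = x_min.iloc[tr].reset_index(drop=True)
    yt = y[tr]
    return {
        "rf": train("rf", xt, yt, FeatureSchema("full"), seed=1),
        "gb": train("gb", xt, yt, FeatureSchema("full"), seed=1),
        "gb_minimal": train("gb", xt_min, yt, FeatureSchema("minimal"), seed=1),
        "dnn": train(
            "dnn", xt, yt, FeatureSchema("full"),
            config=DnnConfig(standardize=True), seed=1,
        ),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
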