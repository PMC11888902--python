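"""Shared fixtures: small deterministic recordings and the two end-to-end
synthetic datasets (class-separated and null) used by the model and
acceptance tests. The expensive datasets are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bcgkit import (
    SyntheticConfig,
    build_feature_table,
    feature_matrix,
    generate_dataset,
    preprocess_pipeline,
    segment_recording,
)

#: study conditions for the end-to-end experiments: 30 recordings per class,
#: 5-minute recordings, fixed seed
STUDY_SEED = 0
STUDY_N_PER_CLASS = 30
STUDY_DURATION_S = 300.0


def clean_config(**overrides) -> SyntheticConfig:
    """A noiseless, strictly periodic generator configuration."""
    base = dict(
        duration_s=10.0,
        heart_rate_bpm_mean={"normotensive": 60.0, "hypertensive": 60.0},
        heart_rate_bpm_sd={"normotensive": 0.0, "hypertensive": 0.0},
        beat_jitter_fraction=0.0,
        resp_amplitude=0.0,
        drift_amplitude=0.0,
        noise_sd=0.0,
        artifact_rate_per_min=0.0,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _pipeline_features(cfg: SyntheticConfig, n_per_class: int):
    recordings = generate_dataset(cfg, n_per_class)
    segments = []
    for rec in recordings:
        segments.extend(segment_recording(preprocess_pipeline(rec)))
    table = build_feature_table(segments)
    return feature_matrix(table)


@pytest.fixture(scope="session")
def separated_features():
    """(X, y, groups) from the default class-separated generator."""
    cfg = SyntheticConfig(duration_s=STUDY_DURATION_S, seed=STUDY_SEED)
    return _pipeline_features(cfg, STUDY_N_PER_CLASS)


@pytest.fixture(scope="session")
def null_features():
    """(X, y, groups) with class-identical generators: labels carry no signal."""
    cfg = SyntheticConfig(
        duration_s=STUDY_DURATION_S, seed=STUDY_SEED
    ).without_class_separation()
    return _pipeline_features(cfg, STUDY_N_PER_CLASS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
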