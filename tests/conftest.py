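"""Shared fixtures: small synthetic datasets and a cheaply trained model."""

import numpy as np
import pytest

from utfbssp import (
    EpochArray,
    FrequencyBand,
    PipelineConfig,
    SourceSpec,
    SyntheticConfig,
    generate,
    train,
)


def small_synth_config(**overrides) -> SyntheticConfig:
    """A scaled-down planted-ERD condition for fast tests."""
    kwargs = dict(
        n_channels=6,
        n_trials_per_class=24,
        fs=250.0,
        trial_duration=1.0,
        sources=(
            SourceSpec(FrequencyBand(8.0, 13.0), 0.5, 1.0),
            SourceSpec(FrequencyBand(14.0, 30.0), 0.5, 1.0),
        ),
        noise_std=0.5,
        mixing_seed=3,
        trial_seed=3,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def null_synth_config(**overrides) -> SyntheticConfig:
    """Same construction but no class difference in any source."""
    sources = tuple(
        SourceSpec(s.band, 1.0, 1.0) for s in small_synth_config().sources
    )
    return small_synth_config(sources=sources, **overrides)


def cheap_pipeline_config(**overrides) -> PipelineConfig:
    kwargs = dict(
        window=(0.0, 1.0),
        n_filters_grid=(2,),
        lambda_fracs=(0.5, 0.2),
        n_folds=3,
        seed=7,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def planted_dataset():
    return generate(small_synth_config())


@pytest.fixture(scope="session")
def trained_model(planted_dataset):
    return train(planted_dataset.epochs, cheap_pipeline_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sinusoid_epochs(freq, fs=250.0, duration=2.0, n_trials=1, n_channels=1,
                    amplitude=1.0, labels=None) -> EpochArray:
    t = np.arange(int(round(fs * duration))) / fs
    sig = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.tile(sig, (n_trials, n_channels, 1))
    if labels is None:
        labels = np.ones(n_trials, dtype=int)
    return EpochArray(data, labels, fs)


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n) * 0.1)
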