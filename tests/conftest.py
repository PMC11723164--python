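import numpy as np
import pandas as pd
import pytest

from adrisk import (
    EpochSet,
    SyntheticConfig,
    default_montage,
    generate_dataset,
    make_trials_meta,
)


@pytest.fixture(scope="session")
def montage12():
    return default_montage(12)


@pytest.fixture(scope="session")
def montage60():
    return default_montage(60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, fs=250.0, t0=-80.0, montage=None, **meta_kwargs):
    """EpochSet from a raw array with broadcastable metadata."""
    data = np.asarray(data, dtype=float)
    montage = montage or default_montage(12)
    n = data.shape[0]
    meta = make_trials_meta(
        subject_id=meta_kwargs.get("subject_id", ["S01"] * n),
        group=meta_kwargs.get("group", "neutral"),
        condition=meta_kwargs.get("condition", "ML"),
        response_time=meta_kwargs.get("response_time", 800.0),
        correct=meta_kwargs.get("correct", True),
    )
    return EpochSet(
        data=data, fs=fs, t0_offset=t0, montage=montage, trials_meta=meta
    )


@pytest.fixture(scope="session")
def small_effect_dataset():
    """12-channel, 6+5-subject dataset with a strong planted beta effect."""
    cfg = SyntheticConfig(
        n_neutral_subjects=6,
        n_risky_subjects=5,
        n_channels=12,
        trials_per_subject_mean=15,
        trials_per_subject_sd=2,
        conditions=("SH",),
        beta_effect=0.4,
        subject_sd=0.1,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def two_condition_dataset():
    """Small two-condition dataset for pipeline-level tests."""
    cfg = SyntheticConfig(
        n_neutral_subjects=7,
        n_risky_subjects=6,
        n_channels=12,
        trials_per_subject_mean=10,
        trials_per_subject_sd=2,
        conditions=("ML", "SH"),
        beta_effect=0.4,
        subject_sd=0.1,
        seed=11,
    )
    return generate_dataset(cfg)
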