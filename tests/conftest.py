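"""Shared fixtures: small synthetic cohorts and reduced model configs."""

import numpy as np
import pytest

from olfeeg import (
    FusionConfig,
    SyntheticConfig,
    TrainParams,
    generate_synthetic_dataset,
    strong_band_gains,
    strong_spatial_mixing,
)


@pytest.fixture(scope="session")
def tiny_trialset():
    """6 subjects x 8 trials, short epochs: fast but structurally complete."""
    cfg = SyntheticConfig(
        n_subjects_per_class=(2, 2, 2),
        trials_per_subject=8,
        epoch_samples=128,
        snr_db=10.0,
        seed=7,
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def strong_trialset():
    """Small cohort with exaggerated class signatures (clean separability)."""
    cfg = SyntheticConfig(
        n_subjects_per_class=(2, 2, 2),
        trials_per_subject=10,
        epoch_samples=256,
        class_band_gains=strong_band_gains(),
        class_spatial_mixing=strong_spatial_mixing(),
        snr_db=20.0,
        seed=3,
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture
def small_fusion_config():
    """Reduced fusion model for fast training tests (short epochs)."""
    return FusionConfig(
        n_eeg_channels=4,
        n_bands=6,
        dw_kernel_time=16,
        dw_padding_time=8,
        pw1_channels=8,
        sep_kernel_time=8,
        sep_padding_time=4,
        pw2_channels=16,
        pre_pool_time=2,
        pool1_time=4,
        pool2_time=2,
        embed_dim=16,
        n_heads=2,
        n_encoder_layers=1,
        head_hidden=(16, 8),
        seed=0,
    )


@pytest.fixture
def fast_train_params():
    return TrainParams(epochs=5, batch_size=16, learning_rate=0.003, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
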