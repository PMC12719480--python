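"""Shared fixtures.

The two expensive fixtures (the full desk-scale pipeline run and the
autoencoder pre-training run) are session-scoped so the end-to-end behaviour
is trained once and inspected by many tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from glioseg import (GAEConfig, PhantomSpec, TrainConfig, build_gae, desk_config,
                     generate_dataset, pretrain_gae, run_pipeline, zscore_normalize)
from glioseg.config import PipelineConfig, derive_seed
from glioseg.detect import ClassifierConfig
from glioseg.gae import reconstruction_mse
from glioseg.preprocess import SplitSpec
from glioseg.segment import UNetConfig


def tiny_config(seed: int = 42) -> PipelineConfig:
    """Smallest complete pipeline: 32x32 slices, 12 subjects, shallow models."""
    return PipelineConfig(
        phantom=PhantomSpec(image_size=32, n_subjects=12, slices_per_subject=3,
                            tumor_prevalence=0.5, tumor_radius_range=(4.0, 7.0),
                            tumor_contrast=0.5, noise_sigma=0.05,
                            background_texture_scale=4.0,
                            seed=derive_seed(seed, "phantom")),
        split=SplitSpec(seed=seed),
        gae=GAEConfig(encoder_depth=2, base_channels=4, latent_channels=8,
                      attention_dim=4),
        classifier=ClassifierConfig(base_channels=4, n_blocks=1),
        segmenter=UNetConfig(depth=2, base_channels=4),
        train=TrainConfig(learning_rate=3e-3, max_epochs=2, patience=2, seed=seed),
        n_augment=0,
        global_seed=seed,
    )


@pytest.fixture(scope="session")
def desk_report():
    """One full desk-scale pipeline run (seed 42), shared across tests."""
    import time

    t0 = time.perf_counter()
    report = run_pipeline(desk_config(42))
    elapsed = time.perf_counter() - t0
    return report, elapsed


@pytest.fixture(scope="session")
def pretrained_gae():
    """GAE pre-trained for 5 epochs on 200 held-constant 64x64 phantoms.

    Returns (model, images, samples, initial_mse, final_mse).
    """
    spec = PhantomSpec(image_size=64, n_subjects=40, slices_per_subject=5,
                       tumor_prevalence=0.5, seed=20260920)
    samples, _ = generate_dataset(spec)
    images = np.stack([zscore_normalize(s.image)[0] for s in samples])
    cfg = desk_config(42)
    model = build_gae(cfg.gae, init_seed=1234, image_size=64)
    initial = reconstruction_mse(model, images)
    model, _hist = pretrain_gae(
        model, images, dataclasses.replace(cfg.train, max_epochs=5))
    final = reconstruction_mse(model, images)
    return model, images, samples, initial, final


@pytest.fixture(scope="session")
def easy_phantoms():
    """Small bank of high-contrast phantoms for unit tests (not training)."""
    spec = PhantomSpec(image_size=64, n_subjects=10, slices_per_subject=3,
                       tumor_prevalence=0.5, seed=7)
    samples, manifest = generate_dataset(spec)
    return spec, samples, manifest
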