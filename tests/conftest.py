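"""Shared fixtures: a small synthetic study reused across module tests.

Everything is generated at test time; the tiny trained model is
session-scoped because CPU training dominates the suite's runtime.
"""

from __future__ import annotations

import pytest

from vocscan.augment import AugmentConfig, augment_dataset
from vocscan.dataset import build_voc_dataset, compute_window_size
from vocscan.nn import ModelConfig, build_model, train_model
from vocscan.synthetic import SyntheticConfig, make_voc_library, synthesize_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_classes=4, n_channels=24, n_scans=1500, n_participants=5,
        samples_per_participant=2, n_env_per_participant=1,
        duration_mean=18.0, duration_sd=3.0, era_shift=12.0, rt_jitter_sd=2.0,
        overlap_pairs=((2, 3, 3),), low_conc_labels=(4,), seed=11)


@pytest.fixture(scope="session")
def tiny_library(tiny_config):
    return make_voc_library(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_library):
    return synthesize_cohort(tiny_config, tiny_library)


@pytest.fixture(scope="session")
def tiny_study(tiny_config, tiny_cohort):
    """Dataset, window size and a trained small 1D VGG on the tiny cohort."""
    cohort, annotations = tiny_cohort
    delta = compute_window_size(annotations)
    dataset = build_voc_dataset(cohort, annotations, delta, seed=5)
    augmented = augment_dataset(dataset, cohort, annotations,
                                AugmentConfig(seed=5), mode="partial")
    cfg = ModelConfig(family="vgg_like", depth=4, filter_mode="1D",
                      n_classes=tiny_config.n_classes + 1, widths=(6, 6, 8),
                      epochs=6, batch_size=32, seed=5)
    trained = train_model(build_model(cfg), augmented, cfg)
    return {"config": tiny_config, "cohort": cohort, "annotations": annotations,
            "delta": delta, "dataset": dataset, "augmented": augmented,
            "model_config": cfg, "trained": trained}
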