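"""Reference experiment configurations at desk scale.

Two ready-made set-ups used by the test suite, the acceptance script and the
examples:

* :func:`recovery_benchmark_config` — the package's standard synthetic
  parameter-recovery experiment: 10 target compounds (one co-eluting pair
  sharing top ions, one low-concentration class), 6 participants with 3
  breath samples each split 12 training / 6 held-out, matrices of 4000
  scans x 128 channels, and a depth-4 1D VGG-like network.  Problem sizes
  are deliberately small enough to train and scan on a single CPU in
  minutes; translation-only augmentation and narrow conv widths (8, 8, 16)
  are the matching desk-scale defaults.

* :func:`bookkeeping_cohort` — a cohort laid out to contain exactly a given
  number of positive window extractions, used to exercise dataset and
  augmentation bookkeeping at full study scale (the canonical 1,868
  positives -> 3,736 data points -> 74,720 / 373,600 augmented) with few
  m/z channels and a narrow window, since the counts do not depend on
  either.
"""

from __future__ import annotations

import numpy as np

from .augment import AugmentConfig
from .io import AbundanceMatrix, VocAnnotation
from .nn.models import ModelConfig
from .pipeline import PipelineConfig
from .synthetic import SyntheticConfig


def recovery_benchmark_config(seed: int = 0) -> PipelineConfig:
    """The standard synthetic end-to-end recovery experiment."""
    return PipelineConfig(
        synthetic=SyntheticConfig(
            n_classes=10, n_channels=128, n_scans=4000,
            n_participants=6, samples_per_participant=3,
            n_env_per_participant=0,
            overlap_pairs=((4, 5, 3),), low_conc_labels=(8,),
            duration_mean=30.0, duration_sd=5.0, rt_jitter_sd=4.0,
            era_shift=30.0),
        augment=AugmentConfig(),
        model=ModelConfig(family="vgg_like", depth=4, filter_mode="1D",
                          widths=(8, 8, 16), epochs=12, batch_size=64),
        augment_mode="partial",
        test_fraction=1.0 / 3.0,
        seed=seed,
    )


def bookkeeping_cohort(n_positives: int = 1868, n_samples: int = 4,
                       n_channels: int = 8, span: int = 10, period: int = 60,
                       n_classes: int = 30,
                       ) -> tuple[list[AbundanceMatrix], list[VocAnnotation]]:
    """A deterministic cohort holding exactly ``n_positives`` annotations.

    Peaks are laid on a regular grid (one per ``period`` rows, each spanning
    ``span + 1`` rows) with plenty of annotation-free gaps for negative
    sampling; labels cycle through ``1..n_classes``.
    """
    per_sample = [n_positives // n_samples] * n_samples
    per_sample[0] += n_positives - sum(per_sample)
    rng = np.random.default_rng(0)
    samples: list[AbundanceMatrix] = []
    annotations: list[VocAnnotation] = []
    for s, count in enumerate(per_sample):
        R = count * period + 2 * period
        values = rng.random((R, n_channels)) + 0.5
        sid = f"BK{s + 1:02d}"
        for i in range(count):
            start = period * i + period // 3
            label = (len(annotations) % n_classes) + 1
            annotations.append(VocAnnotation(sid, label, start,
                                             start + span // 2, start + span))
        samples.append(AbundanceMatrix(values=values, sample_id=sid,
                                       participant_id=f"BP{s % 2 + 1}"))
    return samples, annotations
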