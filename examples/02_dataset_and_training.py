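"""Stage 1: extract the VOC window dataset, augment it and train a 1D CNN.

The window size is computed from the widest annotated elution plus the
translation margin; every positive window is centred on its peak midpoint,
negatives are sampled away from any annotation, 1:1 with positives.
"""

from vocscan import (AugmentConfig, ModelConfig, SyntheticConfig,
                     build_model, build_voc_dataset, compute_window_size,
                     cross_validate, synthesize_cohort, train_model)
from vocscan.augment import augment_dataset

config = SyntheticConfig(
    n_classes=4, n_channels=32, n_scans=2000,
    n_participants=5, samples_per_participant=2, n_env_per_participant=0,
    duration_mean=20, duration_sd=3, rt_jitter_sd=2, seed=7)
cohort, annotations = synthesize_cohort(config)

delta = compute_window_size(annotations)        # widest elution + margin of 19
print(f"window size delta = {delta} rows")

dataset = build_voc_dataset(cohort, annotations, delta, seed=7)
n_pos = sum(p.label > 0 for p in dataset)
print(f"dataset: {len(dataset)} points ({n_pos} positives, "
      f"{len(dataset) - n_pos} negatives)")

augmented = augment_dataset(dataset, cohort, annotations,
                            AugmentConfig(seed=7), mode="partial")
print(f"after translation augmentation: {len(augmented)} points (20x)")

cfg = ModelConfig(family="vgg_like", depth=4, filter_mode="1D",
                  n_classes=config.n_classes + 1, widths=(6, 6, 8),
                  epochs=6, batch_size=32, seed=7)
trained = train_model(build_model(cfg), augmented, cfg)
last = trained.history[-1]
print(f"training: epoch {last['epoch']}  loss {last['loss']:.4f}  "
      f"accuracy {last['accuracy']:.4f}")

mean, sd, _ = cross_validate(augmented, cfg, k=5)
print(f"participant-grouped 5-fold CV accuracy: {mean:.4f} (+/- {sd:.4f})")
print("each fold holds out whole participants, so no windows from one person "
      "appear on both sides of a split")
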