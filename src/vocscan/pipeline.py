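"""End-to-end orchestration: simulate -> dataset -> augment -> train -> scan ->
detect -> evaluate, with one config and one seed.

The split into training and held-out samples is at participant level — every
sample of a held-out participant stays out of the training dataset, mirroring
how a clinical study would separate model building from assessment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, augment_dataset
from .dataset import DEFAULT_MARGIN, build_voc_dataset, compute_window_size
from .detector import apply_duration_rule, detect_vocs, with_confidences
from .errors import ConfigError
from .evaluation import EvalReport, compute_rt_ranges, evaluate_cohort
from .io import save_annotations, save_detections
from .nn.models import ModelConfig, build_model, train_model
from .scanner import scan_sample
from .synthetic import SyntheticConfig, make_voc_library, synthesize_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    gamma: int = 20
    delta: int | None = None          # None -> compute_window_size on training truth
    margin: int = DEFAULT_MARGIN
    test_fraction: float = 1.0 / 3.0
    augment_mode: str = "full"
    rt_ranges_from: str = "all"       # "all" | "train": annotations feeding RT ranges
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.rt_ranges_from not in ("all", "train"):
            raise ConfigError("rt_ranges_from must be 'all' or 'train'")


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2 ** 31) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def run_end_to_end(cfg: PipelineConfig, out_dir: str | Path | None = None
                   ) -> tuple[EvalReport, dict]:
    """Run the whole study at the configured scale; optionally write artefacts.

    Returns the evaluation report and a dict of in-memory artefacts
    (library, cohort, split, window size, trained model, per-sample scans,
    detections).
    """
    t0 = time.time()
    s_synth, s_data, s_aug, s_model, s_split = _stage_seeds(cfg.seed, 5)
    syn = dataclasses.replace(cfg.synthetic, seed=s_synth)
    aug = dataclasses.replace(cfg.augment, seed=s_aug)
    mdl = dataclasses.replace(cfg.model, seed=s_model,
                              n_classes=syn.n_classes + 1)

    library = make_voc_library(syn)
    cohort, annotations = synthesize_cohort(syn, library)
    logger.info("simulated %d samples, %d planted VOCs (%.1fs)",
                len(cohort), len(annotations), time.time() - t0)

    participants = sorted({m.participant_id for m in cohort})
    rng = np.random.default_rng(s_split)
    order = rng.permutation(len(participants))
    n_test = max(1, int(round(cfg.test_fraction * len(participants))))
    test_participants = {participants[i] for i in order[:n_test]}
    train_participants = set(participants) - test_participants
    if not train_participants:
        raise ConfigError("test_fraction leaves no training participants")

    train_samples = [m for m in cohort if m.participant_id in train_participants]
    test_samples = [m for m in cohort if m.participant_id in test_participants]
    train_ids = {m.sample_id for m in train_samples}
    test_ids = {m.sample_id for m in test_samples}
    train_anns = [a for a in annotations if a.sample_id in train_ids]
    test_anns = [a for a in annotations if a.sample_id in test_ids]

    delta = cfg.delta or compute_window_size(train_anns, cfg.margin)
    logger.info("window size delta = %d", delta)

    t1 = time.time()
    dataset = build_voc_dataset(train_samples, train_anns, delta, seed=s_data)
    augmented = augment_dataset(dataset, train_samples, train_anns, aug,
                                mode=cfg.augment_mode)
    logger.info("dataset: %d points -> %d augmented (%.1fs)",
                len(dataset), len(augmented), time.time() - t1)

    t2 = time.time()
    model = build_model(mdl)
    trained = train_model(model, augmented, mdl)
    logger.info("trained %s-%d-%s for %d epochs, final accuracy %.4f (%.1fs)",
                mdl.family, mdl.depth, mdl.filter_mode, len(trained.history),
                trained.history[-1]["accuracy"], time.time() - t2)

    scans, prerule, records = {}, {}, {}
    for m in test_samples:
        ts = time.time()
        scan = scan_sample(trained, m, delta)
        scans[m.sample_id] = scan
        prerule[m.sample_id] = with_confidences(
            apply_duration_rule(scan, cfg.gamma), scan.confidences, cfg.gamma)
        records[m.sample_id] = detect_vocs(scan, cfg.gamma)
        logger.info("scanned %s: %d windows, %d detections (%.1fs)",
                    m.sample_id, scan.n_windows, len(records[m.sample_id]),
                    time.time() - ts)

    era_of_sample = {m.sample_id: m.column_era for m in cohort}
    range_src = annotations if cfg.rt_ranges_from == "all" else train_anns
    report = evaluate_cohort(records, prerule, test_anns, era_of_sample,
                             n_target_classes=syn.n_classes,
                             rt_ranges=compute_rt_ranges(range_src, era_of_sample))
    logger.info("evaluation: %s", report.counts)

    artifacts = {
        "library": library, "cohort": cohort, "annotations": annotations,
        "train_participants": sorted(train_participants),
        "test_participants": sorted(test_participants),
        "delta": delta, "dataset": dataset, "n_augmented": len(augmented),
        "trained_model": trained, "scans": scans, "prerule": prerule,
        "records": records, "report": report,
    }
    if out_dir is not None:
        _write_artifacts(cfg, artifacts, Path(out_dir))
    return report, artifacts


def _write_artifacts(cfg: PipelineConfig, art: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    save_annotations(art["annotations"], out / "annotations.csv")
    import pandas as pd
    pd.DataFrame({
        "label": [p.label for p in art["dataset"]],
        "sample_id": [p.sample_id for p in art["dataset"]],
        "participant_id": [p.participant_id for p in art["dataset"]],
        "source_start": [p.source_start for p in art["dataset"]],
        "center_mu": [p.center_mu for p in art["dataset"]],
    }).to_csv(out / "training_manifest.csv", index=False)
    art["trained_model"].save(out / "model")
    all_records = [r for recs in art["records"].values() for r in recs]
    save_detections(all_records, out / "detections.csv")
    (out / "report.json").write_text(json.dumps({
        "delta": art["delta"],
        "train_participants": art["train_participants"],
        "test_participants": art["test_participants"],
        "n_augmented": art["n_augmented"],
        **art["report"].to_dict(),
    }, indent=1))
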