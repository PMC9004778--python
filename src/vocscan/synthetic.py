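"""Synthetic GC-MS cohorts with planted, annotated VOC peaks.

The generator emulates the structure of a targeted breathomics study so the
whole detection pipeline can be exercised without clinical data:

* each target compound has a fixed ion-fragmentation pattern (relative
  channel ratios, max-normalised to 1) and elutes as a Gaussian envelope in
  scan index, at most ~61 scans wide;
* concentrations are drawn per occurrence on a log10 scale; the library
  spans a >= 1e4 dynamic range, with designated low-concentration classes
  in the bottom decade;
* designated class pairs co-elute and share top ions (the classic
  octane/hexanal-style confounders);
* per-sample RT jitter plus a two-era RT shift model column ageing and the
  one column replacement of a long campaign;
* a constant baseline and i.i.d. half-normal noise keep intensities
  nonnegative without a full shot-noise model.

Annotations are recorded from the noise-free envelope: startRT/endRT are the
first/last scans where the envelope exceeds 1% of its maximum and peakRT is
its argmax.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import AbundanceMatrix, VocAnnotation

logger = logging.getLogger(__name__)

# envelope is cut at 1% of its max, so the recorded elution duration is
# 2 * sqrt(2 ln 100) ~ 6.07 sigma
_CUT_SIGMAS = 2.0 * math.sqrt(2.0 * math.log(100.0))

MAX_ELUTION_SPAN = 61  # scans; widest elution the window size is designed around


@dataclass
class VocLibraryEntry:
    """Per-class generative parameters: ion pattern, elution position and width."""

    label: int
    pattern: np.ndarray            # length-C, relative intensities in [0,1], max = 1
    mean_rt: float                 # row index, era-1 centre
    rt_jitter_sd: float            # scans
    duration_mean: float           # scans
    duration_sd: float             # scans
    log10_conc_range: tuple[float, float]
    era_shift: float               # scans added to mean_rt in era 2

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        if np.count_nonzero(self.pattern) < 2:
            raise ConfigError("pattern needs >= 2 nonzero channels")
        if not math.isclose(float(self.pattern.max()), 1.0):
            raise ConfigError("pattern must be max-normalised to 1")
        if self.duration_mean + 3 * self.duration_sd > MAX_ELUTION_SPAN:
            raise ConfigError(
                f"duration_mean + 3*duration_sd must be <= {MAX_ELUTION_SPAN} scans")


@dataclass
class SyntheticConfig:
    """Cohort-level generative settings.

    Defaults mirror the study conditions this generator emulates: 30 target
    compounds over ~22500 scans x 411 channels at 6.25 Hz, 25 participants
    with 4 breath samples plus one environmental sample each, and a 1e4
    concentration dynamic range.
    """

    n_classes: int = 30
    n_channels: int = 411
    n_scans: int = 22500
    n_participants: int = 25
    samples_per_participant: int = 4
    scan_rate_hz: float = 6.25
    mz_start: int = 40
    baseline_level: float = 10.0
    noise_sd: float = 1.0
    presence_prob: float = 0.9
    overlap_pairs: tuple[tuple[int, int, int], ...] = ()
    low_conc_labels: tuple[int, ...] = ()
    env_labels: tuple[int, ...] | None = None   # None -> every third label
    n_env_per_participant: int = 1
    rt_jitter_sd: float = 4.0
    duration_mean: float = 30.0
    duration_sd: float = 5.0
    era_shift: float = 30.0
    log10_conc_range: tuple[float, float] = (3.5, 5.0)
    low_log10_conc_range: tuple[float, float] = (1.0, 2.0)
    n_pattern_ions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_channels", "n_scans", "n_participants",
                     "samples_per_participant"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.presence_prob <= 1.0:
            raise ConfigError("presence_prob must be in (0, 1]")
        if self.n_pattern_ions < 2 or self.n_pattern_ions > self.n_channels:
            raise ConfigError("n_pattern_ions must be in [2, n_channels]")

    @property
    def env_label_set(self) -> tuple[int, ...]:
        if self.env_labels is not None:
            return self.env_labels
        return tuple(range(3, self.n_classes + 1, 3))

    def era_of_participant(self, index: int) -> int:
        """Column era by participant position: first half era 1, rest era 2."""
        return 1 if index < (self.n_participants + 1) // 2 else 2


def _make_pattern(rng: np.random.Generator, n_channels: int, n_ions: int) -> np.ndarray:
    channels = rng.choice(n_channels, size=n_ions, replace=False)
    pattern = np.zeros(n_channels)
    pattern[channels] = rng.uniform(0.05, 0.9, size=n_ions)
    pattern[channels[0]] = 1.0   # base peak
    return pattern


def make_voc_library(config: SyntheticConfig) -> list[VocLibraryEntry]:
    """Build the per-class library: patterns, elution positions, concentration ranges.

    Labels are assigned in elution order (strictly increasing ``mean_rt``).
    Each overlap pair (a, b, shared) shares ``shared`` of its 5 strongest
    ions and is forced to co-elute (|mean_rt difference| < duration_mean);
    pairs must be consecutive labels so elution order is preserved.
    """
    J = config.n_classes
    if J < 2:
        raise ConfigError("need at least 2 target classes")
    for a, b, k in config.overlap_pairs:
        if not (1 <= a <= J and 1 <= b <= J):
            raise ConfigError(f"overlap pair ({a},{b}) out of label range 1..{J}")
        if abs(a - b) != 1:
            raise ConfigError(
                "overlap pair labels must be consecutive in elution order")
        if not 0 < k <= 5:
            raise ConfigError("shared top-ion count must be in 1..5")
    for lab in config.low_conc_labels:
        if not 1 <= lab <= J:
            raise ConfigError(f"low_conc label {lab} out of range 1..{J}")

    rng = np.random.default_rng(config.seed)
    R = config.n_scans

    # evenly spread elution centres with a little jitter, kept sorted
    base = np.linspace(0.08 * R, 0.92 * R, J)
    gap = (0.92 - 0.08) * R / max(J - 1, 1)
    centres = np.sort(base + rng.uniform(-0.2 * gap, 0.2 * gap, size=J))

    patterns = [_make_pattern(rng, config.n_channels, config.n_pattern_ions)
                for _ in range(J)]

    for a, b, k in config.overlap_pairs:
        ia, ib = a - 1, b - 1
        a_top5 = set(np.argsort(patterns[ia])[::-1][:5].tolist())
        # rebuild b's pattern avoiding a's top-5 entirely, then inject k shared ions
        avail = np.setdiff1d(np.arange(config.n_channels), list(a_top5))
        own = rng.choice(avail, size=config.n_pattern_ions - k, replace=False)
        pat = np.zeros(config.n_channels)
        pat[own] = rng.uniform(0.05, 0.45, size=own.size)
        shared = sorted(a_top5, key=lambda c: -patterns[ia][c])[:k]
        pat[shared] = np.linspace(1.0, 0.6, num=k)
        patterns[ib] = pat
        # force co-elution: centres within one elution width
        offset = rng.uniform(0.3, 0.8) * config.duration_mean
        centres[ib] = centres[ia] + (offset if ib > ia else -offset)

    low = set(config.low_conc_labels)
    library = []
    for j in range(1, J + 1):
        library.append(VocLibraryEntry(
            label=j,
            pattern=patterns[j - 1],
            mean_rt=float(centres[j - 1]),
            rt_jitter_sd=config.rt_jitter_sd,
            duration_mean=config.duration_mean,
            duration_sd=config.duration_sd,
            log10_conc_range=(config.low_log10_conc_range if j in low
                              else config.log10_conc_range),
            era_shift=config.era_shift,
        ))
    return library


def _plant_peak(matrix: np.ndarray, entry: VocLibraryEntry, rng: np.random.Generator,
                era: int, low_conc: bool,
                low_range: tuple[float, float]) -> VocAnnotation | None:
    """Add one Gaussian-envelope peak; return its annotation or None if skipped."""
    R = matrix.shape[0]
    mu = entry.mean_rt + (entry.era_shift if era == 2 else 0.0) \
        + rng.normal(0.0, entry.rt_jitter_sd)
    duration = rng.normal(entry.duration_mean, entry.duration_sd)
    duration = float(np.clip(duration, 5.0,
                             entry.duration_mean + 3 * entry.duration_sd))
    sigma = duration / _CUT_SIGMAS
    lo = int(math.floor(mu - duration / 2.0))
    hi = int(math.ceil(mu + duration / 2.0))
    rows = np.arange(lo, hi + 1)
    envelope = np.exp(-0.5 * ((rows - mu) / sigma) ** 2)
    keep = envelope > 0.01 * envelope.max()
    rows, envelope = rows[keep], envelope[keep]
    if rows.size == 0 or rows[0] < 0 or rows[-1] >= R:
        logger.warning("class %d peak at mu=%.1f falls outside [0, %d); skipped",
                       entry.label, mu, R)
        return None
    conc_range = low_range if low_conc else entry.log10_conc_range
    conc = 10.0 ** rng.uniform(*conc_range)
    matrix[rows] += conc * np.outer(envelope, entry.pattern)
    peak = int(rows[np.argmax(envelope)])
    return VocAnnotation(sample_id="", label=entry.label,
                         startRT=int(rows[0]), peakRT=peak, endRT=int(rows[-1]))


def synthesize_sample(library: Sequence[VocLibraryEntry], config: SyntheticConfig,
                      participant_id: str, era: int, *, sample_id: str,
                      sample_kind: str = "breath",
                      rng: np.random.Generator | None = None,
                      seed: int | None = None,
                      ) -> tuple[AbundanceMatrix, list[VocAnnotation]]:
    """Generate one abundance matrix with planted peaks and its annotations.

    Breath samples plant each library class independently with probability
    ``presence_prob``; environmental samples plant only ``env_label_set``
    classes, at low concentration.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    matrix = np.zeros((config.n_scans, config.n_channels))
    env = sample_kind == "environmental"
    allowed = set(config.env_label_set) if env else None

    annotations: list[VocAnnotation] = []
    for entry in library:
        if env and entry.label not in allowed:
            continue
        if rng.random() >= config.presence_prob:
            continue
        ann = _plant_peak(matrix, entry, rng, era,
                          low_conc=env, low_range=config.low_log10_conc_range)
        if ann is not None:
            annotations.append(VocAnnotation(sample_id=sample_id, label=ann.label,
                                             startRT=ann.startRT, peakRT=ann.peakRT,
                                             endRT=ann.endRT))
    if config.baseline_level:
        matrix += config.baseline_level
    if config.noise_sd:
        matrix += np.abs(rng.normal(0.0, config.noise_sd, size=matrix.shape))
    m = AbundanceMatrix(values=matrix, sample_id=sample_id,
                        participant_id=participant_id,
                        scan_rate_hz=config.scan_rate_hz, mz_start=config.mz_start,
                        column_era=era, sample_kind=sample_kind)
    return m, annotations


def synthesize_cohort(config: SyntheticConfig,
                      library: Sequence[VocLibraryEntry] | None = None,
                      ) -> tuple[list[AbundanceMatrix], list[VocAnnotation]]:
    """Generate the full cohort: breath samples per participant plus environmental ones.

    All samples of one participant share a participant_id and column era.
    Reproducible for a fixed ``config.seed``.
    """
    if library is None:
        library = make_voc_library(config)
    seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_participants * (config.samples_per_participant
                                 + config.n_env_per_participant))
    samples: list[AbundanceMatrix] = []
    annotations: list[VocAnnotation] = []
    si = 0
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        era = config.era_of_participant(p)
        for b in range(config.samples_per_participant):
            sid = f"{pid}-BS{b + 1:02d}"
            m, anns = synthesize_sample(library, config, pid, era, sample_id=sid,
                                        rng=np.random.default_rng(seeds[si]))
            si += 1
            samples.append(m)
            annotations.extend(anns)
        for e in range(config.n_env_per_participant):
            sid = f"{pid}-ENV{e + 1:02d}"
            m, anns = synthesize_sample(library, config, pid, era, sample_id=sid,
                                        sample_kind="environmental",
                                        rng=np.random.default_rng(seeds[si]))
            si += 1
            samples.append(m)
            annotations.extend(anns)
    return samples, annotations
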