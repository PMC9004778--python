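"""Dataset augmentation: RT translation, intensity variation, normalisation.

Two operators enlarge the training set without disturbing the ion pattern:

* *translation along RT* re-extracts each window at 20 shifted start
  positions (-9..+10 scans), presenting the peak at different offsets, as
  the scanner will see it;
* *intensity variation* multiplies the rows inside the elution interval by
  a Gaussian-shaped factor G_x = exp(-((x - mu)^2) / (2 sigma^2)) * r + 1
  with r ~ U(0, 0.1), emulating concentration variation while preserving
  relative channel ratios exactly; rows at or outside the interval
  boundaries are untouched.

Combined (20 translations x (1 original + 4 intensity variants)) they grow
the dataset 100-fold.  Every emitted window is min-max normalised to [0, 1].

The Gaussian width sigma is not a property of the data but of the operator;
it defaults to (endRT - startRT)/6 so that +/-3 sigma spans the elution
interval and the factor tapers to ~1 at its boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .dataset import VocDataPoint, center_of
from .errors import ConfigError, ValidationError
from .io import AbundanceMatrix, VocAnnotation

logger = logging.getLogger(__name__)


@dataclass
class AugmentConfig:
    shift_min: int = -9
    shift_max: int = 10
    n_intensity_variants: int = 4
    r_max: float = 0.1              # r drawn from the open interval (0, r_max)
    sigma_fraction: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_max < self.shift_min:
            raise ConfigError("shift_max must be >= shift_min")
        if self.n_intensity_variants < 0:
            raise ConfigError("n_intensity_variants must be >= 0")
        if not 0.0 < self.r_max < 1.0:
            raise ConfigError("r_max must be in (0, 1)")

    @property
    def n_shifts(self) -> int:
        return self.shift_max - self.shift_min + 1


def translate_rt(m: AbundanceMatrix, a: VocAnnotation, delta: int,
                 cfg: AugmentConfig | None = None) -> list[VocDataPoint]:
    """Re-extract the window at every shifted start k + n, n in [shift_min, shift_max].

    Shift 0 reproduces the centred extraction.  Shifts whose window leaves the
    matrix are dropped with a warning.
    """
    cfg = cfg or AugmentConfig()
    mu = center_of(a)
    k0 = mu - delta // 2
    out: list[VocDataPoint] = []
    dropped = 0
    for n in range(cfg.shift_min, cfg.shift_max + 1):
        k = k0 + n
        if k < 0 or k + delta > m.n_scans:
            dropped += 1
            continue
        out.append(VocDataPoint(window=m.values[k:k + delta].copy(), label=a.label,
                                sample_id=m.sample_id, participant_id=m.participant_id,
                                source_start=k, center_mu=mu))
    if dropped:
        logger.warning("dropped %d of %d shifts at matrix edge for annotation mu=%d",
                       dropped, cfg.n_shifts, mu)
    return out


def gaussian_multiplier(x: np.ndarray, a: VocAnnotation, r: float,
                        sigma_fraction: float) -> np.ndarray:
    """The per-row factor G_x: Gaussian bump of height 1 + r strictly inside
    (startRT, endRT), exactly 1 elsewhere."""
    mu = (a.startRT + a.endRT) / 2.0
    sigma = sigma_fraction * (a.endRT - a.startRT)
    g = np.ones_like(x, dtype=float)
    inside = (x > a.startRT) & (x < a.endRT)
    if sigma > 0:
        g[inside] = np.exp(-0.5 * ((x[inside] - mu) / sigma) ** 2) * r + 1.0
    return g


def intensity_variation(p: VocDataPoint, a: VocAnnotation,
                        cfg: AugmentConfig | None = None,
                        r: float | None = None,
                        rng: np.random.Generator | None = None) -> VocDataPoint:
    """Scale rows inside the elution interval by G_x; channel ratios are preserved."""
    cfg = cfg or AugmentConfig()
    if r is None:
        rng = rng or np.random.default_rng(cfg.seed)
        r = float(rng.uniform(0.0, cfg.r_max))
        while r == 0.0:             # open interval
            r = float(rng.uniform(0.0, cfg.r_max))
    elif not 0.0 < r < 1.0:
        raise ValueError(f"r must be in (0, 1), got {r}")
    x = p.source_start + np.arange(p.delta)
    g = gaussian_multiplier(x, a, r, cfg.sigma_fraction)
    return VocDataPoint(window=p.window * g[:, None], label=p.label,
                        sample_id=p.sample_id, participant_id=p.participant_id,
                        source_start=p.source_start, center_mu=p.center_mu)


def normalize_datapoint(p: VocDataPoint) -> VocDataPoint:
    """Per-data-point min-max scaling to [0, 1]; a constant window maps to zeros."""
    w = np.asarray(p.window, dtype=np.float32)
    if not np.all(np.isfinite(w)):
        raise ValidationError("window contains non-finite values")
    lo, hi = float(w.min()), float(w.max())
    scaled = np.zeros_like(w) if hi == lo else (w - lo) / (hi - lo)
    return VocDataPoint(window=scaled, label=p.label, sample_id=p.sample_id,
                        participant_id=p.participant_id,
                        source_start=p.source_start, center_mu=p.center_mu)


AugmentMode = Literal["full", "partial", "none"]


def augment_dataset(dataset: Sequence[VocDataPoint],
                    cohort: Sequence[AbundanceMatrix] | Mapping[str, AbundanceMatrix],
                    annotations: Sequence[VocAnnotation],
                    cfg: AugmentConfig | None = None,
                    mode: AugmentMode = "full") -> list[VocDataPoint]:
    """Expand and normalise the dataset.

    ``full``: 20 translations x (original + 4 intensity variants) = 100x.
    ``partial``: 20 translations only.
    ``none``: normalisation only.

    Negatives carry no elution interval, so their "intensity variants" are
    identity copies; the translation re-extraction still shifts their content.
    """
    cfg = cfg or AugmentConfig()
    if mode not in ("full", "partial", "none"):
        raise ConfigError(f"unknown augmentation mode {mode!r}")
    matrices = (cohort if isinstance(cohort, Mapping)
                else {m.sample_id: m for m in cohort})
    ann_by_key = {(a.sample_id, a.label, center_of(a)): a for a in annotations}
    rng = np.random.default_rng(cfg.seed)

    out: list[VocDataPoint] = []
    for p in dataset:
        if mode == "none":
            out.append(normalize_datapoint(p))
            continue
        m = matrices[p.sample_id]
        ann = ann_by_key.get((p.sample_id, p.label, p.center_mu))
        if p.label > 0 and ann is None:
            raise ValidationError(
                f"no annotation found for positive data point "
                f"({p.sample_id}, label {p.label}, mu {p.center_mu})")
        delta = p.delta
        for n in range(cfg.shift_min, cfg.shift_max + 1):
            k = p.source_start + n
            if k < 0 or k + delta > m.n_scans:
                logger.warning("shift %+d out of bounds for %s (start %d); dropped",
                               n, p.sample_id, p.source_start)
                continue
            shifted = VocDataPoint(window=m.values[k:k + delta], label=p.label,
                                   sample_id=p.sample_id,
                                   participant_id=p.participant_id,
                                   source_start=k, center_mu=p.center_mu)
            out.append(normalize_datapoint(shifted))
            if mode == "full":
                for _ in range(cfg.n_intensity_variants):
                    if p.label > 0:
                        v = intensity_variation(shifted, ann, cfg, rng=rng)
                    else:
                        v = shifted    # pattern-free: identity variant
                    out.append(normalize_datapoint(v))
    return out
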