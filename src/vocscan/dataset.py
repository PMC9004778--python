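"""Stage-1 dataset construction: window size, positive extraction, negative sampling.

A data point is a delta x C sub-matrix of one abundance matrix.  Positives are
centred on the midpoint mu = floor((startRT + endRT) / 2) of an annotated
elution interval so that mu sits at window row delta/2.  Negatives are windows
whose row interval intersects no annotated interval; the built dataset always
holds exactly as many negatives as positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ExtractionError, SamplingError
from .io import AbundanceMatrix, VocAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 19  # extra rows beyond the widest elution, for +/-9..+10 translation


@dataclass
class VocDataPoint:
    """One delta x C window with its class label and provenance."""

    window: np.ndarray
    label: int
    sample_id: str
    participant_id: str
    source_start: int      # row k of the extraction window in the source matrix
    center_mu: int         # row index mu the window is centred on

    @property
    def delta(self) -> int:
        return self.window.shape[0]


def compute_window_size(annotations: Sequence[VocAnnotation],
                        margin: int = DEFAULT_MARGIN) -> int:
    """Window size delta = max inclusive elution span + margin, rounded up to even.

    The margin leaves room for translation augmentation; with the canonical
    margin of 19 a maximal ~61-row elution yields delta = 80.
    """
    if not annotations:
        raise ValueError("cannot compute window size from an empty annotation list")
    delta = max(a.endRT - a.startRT + 1 for a in annotations) + margin
    return delta + (delta % 2)


def center_of(a: VocAnnotation) -> int:
    """Midpoint of the elution interval; floor for odd startRT + endRT."""
    return (a.startRT + a.endRT) // 2


def extract_datapoint(m: AbundanceMatrix, a: VocAnnotation, delta: int) -> VocDataPoint:
    """Extract the window of rows [mu - delta/2, mu + delta/2) around annotation ``a``."""
    mu = center_of(a)
    k = mu - delta // 2
    if k < 0 or k + delta > m.n_scans:
        raise ExtractionError(
            f"window [{k}, {k + delta}) for annotation at mu={mu} exceeds "
            f"matrix bounds [0, {m.n_scans})")
    return VocDataPoint(window=m.values[k:k + delta].copy(), label=a.label,
                        sample_id=m.sample_id, participant_id=m.participant_id,
                        source_start=k, center_mu=mu)


def eligible_negative_starts(m: AbundanceMatrix,
                             annotations: Sequence[VocAnnotation],
                             delta: int) -> np.ndarray:
    """Start indices k whose window [k, k+delta) intersects no annotated interval."""
    R = m.n_scans
    if R < delta:
        return np.empty(0, dtype=int)
    occupied = np.zeros(R, dtype=bool)
    for a in annotations:
        occupied[a.startRT:a.endRT + 1] = True
    # window k is eligible iff no occupied row in [k, k+delta)
    csum = np.concatenate([[0], np.cumsum(occupied)])
    window_hits = csum[delta:] - csum[:-delta]     # length R - delta + 1
    return np.flatnonzero(window_hits == 0)


def sample_negatives(m: AbundanceMatrix, annotations: Sequence[VocAnnotation],
                     delta: int, count: int,
                     seed: int | np.random.Generator = 0) -> list[VocDataPoint]:
    """Draw ``count`` negative-class windows uniformly without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = eligible_negative_starts(m, annotations, delta)
    if starts.size < count:
        raise SamplingError(
            f"requested {count} negatives but only {starts.size} eligible "
            f"positions in sample {m.sample_id}")
    chosen = rng.choice(starts, size=count, replace=False)
    return [VocDataPoint(window=m.values[k:k + delta].copy(), label=0,
                         sample_id=m.sample_id, participant_id=m.participant_id,
                         source_start=int(k), center_mu=int(k) + delta // 2)
            for k in sorted(chosen.tolist())]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        raise SamplingError("no eligible negative positions in any sample")
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def build_voc_dataset(cohort: Sequence[AbundanceMatrix],
                      annotations: Sequence[VocAnnotation],
                      delta: int, seed: int = 0) -> list[VocDataPoint]:
    """All extractable positives plus an equal number of negatives.

    Negatives are spread across samples proportionally to each sample's count
    of eligible window positions.  Positives whose window would cross a matrix
    edge are skipped (not padded).
    """
    rng = np.random.default_rng(seed)
    by_sample: dict[str, list[VocAnnotation]] = {m.sample_id: [] for m in cohort}
    for a in annotations:
        by_sample.setdefault(a.sample_id, []).append(a)

    positives: list[VocDataPoint] = []
    skipped = 0
    for m in cohort:
        for a in by_sample.get(m.sample_id, []):
            try:
                positives.append(extract_datapoint(m, a, delta))
            except ExtractionError:
                skipped += 1
    if skipped:
        logger.warning("skipped %d edge annotations whose window left the matrix",
                       skipped)
    if not positives:
        logger.warning("no extractable annotations; returning an empty dataset")
        return []

    eligible = {m.sample_id: eligible_negative_starts(m, by_sample.get(m.sample_id, []),
                                                      delta)
                for m in cohort}
    weights = np.array([eligible[m.sample_id].size for m in cohort], dtype=float)
    counts = _largest_remainder(weights, len(positives))
    # cap at availability, redistribute any shortfall
    for _ in range(len(cohort)):
        over = counts - weights.astype(int)
        if (over <= 0).all():
            break
        excess = int(over[over > 0].sum())
        counts = np.minimum(counts, weights.astype(int))
        room = weights.astype(int) - counts
        counts += _largest_remainder(np.where(room > 0, room, 0).astype(float), excess)

    negatives: list[VocDataPoint] = []
    for m, c in zip(cohort, counts):
        if c:
            negatives.extend(sample_negatives(m, by_sample.get(m.sample_id, []),
                                              delta, int(c), seed=rng))
    return positives + negatives


# ---------------------------------------------------------------------------
# persistence: windows in one .npz + a CSV manifest

def save_dataset(points: Sequence[VocDataPoint], windows_path, manifest_path) -> None:
    import pandas as pd
    np.savez_compressed(windows_path,
                        windows=np.stack([p.window for p in points]).astype(np.float32))
    pd.DataFrame({
        "label": [p.label for p in points],
        "sample_id": [p.sample_id for p in points],
        "participant_id": [p.participant_id for p in points],
        "source_start": [p.source_start for p in points],
        "center_mu": [p.center_mu for p in points],
    }).to_csv(manifest_path, index=False)


def load_dataset(windows_path, manifest_path) -> list[VocDataPoint]:
    import pandas as pd
    windows = np.load(windows_path)["windows"]
    manifest = pd.read_csv(manifest_path)
    return [VocDataPoint(window=windows[i], label=int(r.label), sample_id=str(r.sample_id),
                         participant_id=str(r.participant_id),
                         source_start=int(r.source_start), center_mu=int(r.center_mu))
            for i, r in enumerate(manifest.itertuples())]
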