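"""Stage-2 phase B: turn the scan sequences into a final detection list.

Three chromatographic constraints are applied in turn:

* **duration rule** — a compound elutes over many consecutive scans, so only
  maximal constant-label runs of length >= gamma (default 20, matching the
  window margin) count as detections;
* **order rule** — compounds leave the GC column in a known elution order;
  a detection contradicted by three distinct later-starting lower labels
  (or three earlier-starting higher labels) is removed, in a single pass
  over the original detection set;
* **uniqueness rule** — a compound elutes once per run, so among same-label
  detections only the one with the highest detection confidence survives
  (ties -> earlier start).

Detection confidence is the maximum length-gamma moving average of the
per-window confidences inside the run.  A detection's RT interval maps each
window to the RT of its middle row: DI = [l + delta/2, l + n - 1 + delta/2].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import DetectionRecord
from .scanner import ScanResult

DEFAULT_GAMMA = 20


@dataclass(frozen=True)
class Detection:
    """One phase-B candidate: a constant-label run of scan windows."""

    label: int
    start_index: int          # l: index of the first window in the run
    length: int               # n: number of windows
    delta: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("detections carry labels >= 1")
        if self.length < 1:
            raise ValueError("run length must be >= 1")

    @property
    def sRT(self) -> int:
        return self.start_index + self.delta // 2

    @property
    def eRT(self) -> int:
        return self.start_index + self.length - 1 + self.delta // 2


def detection_interval(d: Detection) -> tuple[int, int]:
    """DI(d) = [sRT, eRT] in row-index units; its length equals the run length."""
    return (d.sRT, d.eRT)


def label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a label sequence as (label, start, length)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def apply_duration_rule(scan: ScanResult, gamma: int = DEFAULT_GAMMA
                        ) -> list[Detection]:
    """One Detection per maximal run with label > 0 and length >= gamma."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    return [Detection(label=lab, start_index=s, length=n, delta=scan.delta)
            for lab, s, n in label_runs(scan.labels)
            if lab > 0 and n >= gamma]


def detection_confidence(d: Detection, confidences: np.ndarray,
                         gamma: int = DEFAULT_GAMMA) -> float:
    """Maximum mean over all length-gamma contiguous sub-runs of the detection."""
    if d.length < gamma:
        raise ValueError(f"run of length {d.length} is shorter than gamma={gamma}")
    seg = np.asarray(confidences, dtype=float)[d.start_index:d.start_index + d.length]
    means = np.convolve(seg, np.full(gamma, 1.0 / gamma), mode="valid")
    return float(means.max())


def with_confidences(detections: Sequence[Detection], confidences: np.ndarray,
                     gamma: int = DEFAULT_GAMMA) -> list[Detection]:
    return [replace(d, confidence=detection_confidence(d, confidences, gamma))
            for d in detections]


def apply_order_rule(detections: Sequence[Detection]) -> list[Detection]:
    """Drop detections contradicted by three distinct-label witnesses.

    A detection with label f is removed when there exist three detections
    with three distinct labels all < f starting at or after it, or three
    distinct labels all > f starting at or before it (the linear order by
    sRT is non-strict, so equal-sRT detections witness each other).
    Evaluated once against the original set, not iterated.
    """
    dets = list(detections)
    kept = []
    for d in dets:
        later_lower = {o.label for o in dets
                       if o is not d and o.sRT >= d.sRT and o.label < d.label}
        earlier_higher = {o.label for o in dets
                          if o is not d and o.sRT <= d.sRT and o.label > d.label}
        if len(later_lower) < 3 and len(earlier_higher) < 3:
            kept.append(d)
    return kept


def apply_uniqueness_rule(detections: Sequence[Detection]) -> list[Detection]:
    """Keep at most one detection per label: highest confidence, ties -> earlier sRT."""
    best: dict[int, Detection] = {}
    for d in detections:
        if d.confidence is None:
            raise ValueError("uniqueness rule needs detection confidences")
        cur = best.get(d.label)
        if (cur is None or d.confidence > cur.confidence
                or (d.confidence == cur.confidence and d.sRT < cur.sRT)):
            best[d.label] = d
    return sorted(best.values(), key=lambda d: (d.sRT, d.label))


def detect_vocs(scan: ScanResult, gamma: int = DEFAULT_GAMMA
                ) -> list[DetectionRecord]:
    """Full phase B: duration -> confidence -> order -> uniqueness, sRT-sorted."""
    d_a = with_confidences(apply_duration_rule(scan, gamma), scan.confidences, gamma)
    d_tilde = apply_order_rule(d_a)
    d_final = apply_uniqueness_rule(d_tilde)
    return [DetectionRecord(sample_id=scan.sample_id, label=d.label,
                            sRT=d.sRT, eRT=d.eRT, confidence=d.confidence)
            for d in sorted(d_final, key=lambda d: (d.sRT, d.label))]
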