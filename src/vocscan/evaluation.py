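"""Evaluation of the automated analysis against (noisy) expert ground truth.

Two complementary schemes:

1. **Localisation + classification** — a detection is a true positive (TP)
   when its label matches an annotation of the sample and its RT interval
   overlaps the annotated elution interval; otherwise it is a false
   positive, and an unmatched annotation is a false negative.  Because the
   ground truth itself comes from a subjective deconvolution workflow, false
   positives that fall inside the compound's characteristic RT range
   (computed per column era from all its ground-truth peak positions) are
   reclassified as *tentative true positives* (TTP) — the probability that a
   random false detection lands inside such a narrow range is bounded by
   P_max = (max |RTrange| + max |DI|) / (R - max |DI|), a few percent.
   False negatives whose class has a TTP elsewhere in the same sample
   become *tentative true negatives* (TTN).

2. **Presence** — per (sample, class) only presence matters; this yields
   well-defined true negatives and hence a specificity.

Sensitivity and specificity are reported against two benchmarks: *expert*
(TTP counted as FP, TTN as FN) and *system-derived correction* (TTP as TP,
TTN as TN).  Ranked-detection quality is summarised per class by average
precision (non-interpolated rectangle sum over the confidence-ranked list)
and overall by its unweighted mean (mAP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detector import Detection, detection_interval
from .errors import UndefinedMetricError, ValidationError
from .io import DetectionRecord, VocAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RTRange:
    """Characteristic RT range of one class in one column era: [min, max] peakRT."""

    label: int
    era: int
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError("RT range needs lo <= hi")

    @property
    def length(self) -> int:
        return self.hi - self.lo

    def intersects(self, interval: tuple[int, int]) -> bool:
        return interval[0] <= self.hi and self.lo <= interval[1]


def compute_rt_ranges(annotations: Sequence[VocAnnotation],
                      era_of_sample: Mapping[str, int]
                      ) -> dict[tuple[int, int], RTRange]:
    """Per (label, era): [min, max] of peakRT over all ground-truth instances."""
    grouped: dict[tuple[int, int], list[int]] = {}
    for a in annotations:
        era = era_of_sample[a.sample_id]
        grouped.setdefault((a.label, era), []).append(a.peakRT)
    return {key: RTRange(label=key[0], era=key[1], lo=min(v), hi=max(v))
            for key, v in grouped.items()}


# ---------------------------------------------------------------------------
# scheme 1: localisation + classification


@dataclass
class MatchResult:
    """Pre-tentative scheme-1 outcome for one sample."""

    tp: list[tuple[DetectionRecord, VocAnnotation]] = field(default_factory=list)
    fp: list[DetectionRecord] = field(default_factory=list)
    fn: list[VocAnnotation] = field(default_factory=list)


def match_detections(records: Sequence[DetectionRecord],
                     annotations: Sequence[VocAnnotation]) -> MatchResult:
    """TP iff label matches and [sRT, eRT] overlaps the annotation interval."""
    labels = [r.label for r in records]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate labels in detection records; "
                              "uniqueness rule violated upstream")
    res = MatchResult()
    matched: set[int] = set()
    for r in records:
        hit = None
        for i, a in enumerate(annotations):
            if i in matched or a.label != r.label:
                continue
            if r.sRT <= a.endRT and a.startRT <= r.eRT:
                hit = i
                break
        if hit is None:
            res.fp.append(r)
        else:
            matched.add(hit)
            res.tp.append((r, annotations[hit]))
    res.fn = [a for i, a in enumerate(annotations) if i not in matched]
    return res


@dataclass
class Scheme1Outcome:
    """Scheme-1 categories after tentative reclassification, for one sample."""

    tp: list[tuple[DetectionRecord, VocAnnotation]] = field(default_factory=list)
    ttp: list[DetectionRecord] = field(default_factory=list)
    fp: list[DetectionRecord] = field(default_factory=list)
    ttn: list[VocAnnotation] = field(default_factory=list)
    fn: list[VocAnnotation] = field(default_factory=list)


def reclassify_tentatives(prerule_detections: Sequence[Detection],
                          match: MatchResult,
                          rt_ranges: Mapping[int, RTRange]) -> Scheme1Outcome:
    """Promote FP->TTP (detection inside its class range, judged on the
    pre-order/pre-uniqueness set) and the matching FN->TTN.

    ``rt_ranges`` maps label -> RTRange for the sample's column era.
    """
    out = Scheme1Outcome(tp=list(match.tp))
    for r in match.fp:
        rng = rt_ranges.get(r.label)
        if rng is None:
            logger.warning("no RT range for detected class %d; FP kept certain",
                           r.label)
            out.fp.append(r)
            continue
        candidates = [d for d in prerule_detections if d.label == r.label]
        if any(rng.intersects(detection_interval(d)) for d in candidates):
            out.ttp.append(r)
        else:
            out.fp.append(r)
    ttp_labels = {r.label for r in out.ttp}
    for a in match.fn:
        (out.ttn if a.label in ttp_labels else out.fn).append(a)
    return out


def p_intersect(range_len: float, interval_len: float, R: float) -> float:
    """P(random interval of length |I| intersects a fixed range) =
    (|range| + |I|) / (R - |I|)."""
    if interval_len < 0 or range_len < 0:
        raise ValueError("lengths must be nonnegative")
    if interval_len >= R:
        raise ValueError("interval length must be smaller than the RT dimension")
    return (range_len + interval_len) / (R - interval_len)


def p_max_bound(rt_ranges: Iterable[RTRange],
                detections: Iterable[Detection | DetectionRecord],
                R: float) -> float:
    """Upper bound on the probability that a random detection lands inside a
    compatible RT range: maxima over all ranges and all detection intervals."""
    range_lens = [r.length for r in rt_ranges]
    di_lens = [d.eRT - d.sRT for d in detections]
    if not range_lens or not di_lens:
        raise ValueError("need at least one RT range and one detection")
    return p_intersect(max(range_lens), max(di_lens), R)


# ---------------------------------------------------------------------------
# scheme 2: presence


def presence_confusion(records: Sequence[DetectionRecord],
                       annotations: Sequence[VocAnnotation],
                       rt_ranges: Mapping[int, RTRange],
                       n_target_classes: int) -> dict[int, str]:
    """Per class for one sample: 'TN', 'FP*', 'TTP*', 'TP' or 'FN' (presence)."""
    det_by_label: dict[int, list[DetectionRecord]] = {}
    for r in records:
        det_by_label.setdefault(r.label, []).append(r)
    truth_labels = {a.label for a in annotations}
    out: dict[int, str] = {}
    for j in range(1, n_target_classes + 1):
        detected, present = j in det_by_label, j in truth_labels
        if not detected and not present:
            out[j] = "TN"
        elif detected and present:
            out[j] = "TP"
        elif detected:
            rng = rt_ranges.get(j)
            inside = rng is not None and any(
                rng.intersects((r.sRT, r.eRT)) for r in det_by_label[j])
            out[j] = "TTP*" if inside else "FP*"
        else:
            out[j] = "FN"
    return out


# ---------------------------------------------------------------------------
# metrics


def sensitivity(counts: Mapping[str, int], benchmark: str = "expert") -> float:
    """expert: TP/(TP+FN+TTN);  corrected: (TP+TTP)/(TP+TTP+FN)."""
    tp, ttp = counts.get("tp", 0), counts.get("ttp", 0)
    fn, ttn = counts.get("fn", 0), counts.get("ttn", 0)
    if benchmark == "expert":
        denom = tp + fn + ttn
        num = tp
    elif benchmark == "corrected":
        denom = tp + ttp + fn
        num = tp + ttp
    else:
        raise ValueError(f"unknown benchmark {benchmark!r}")
    if denom == 0:
        raise UndefinedMetricError("sensitivity denominator is zero")
    return num / denom


def specificity(counts: Mapping[str, int], benchmark: str = "expert") -> float:
    """expert: TN/(TN+FP*+TTP*);  corrected: TN/(TN+FP*)."""
    tn = counts.get("tn", 0)
    fp_star, ttp_star = counts.get("fp_star", 0), counts.get("ttp_star", 0)
    if benchmark == "expert":
        denom = tn + fp_star + ttp_star
    elif benchmark == "corrected":
        denom = tn + fp_star
    else:
        raise ValueError(f"unknown benchmark {benchmark!r}")
    if denom == 0:
        raise UndefinedMetricError("specificity denominator is zero")
    return tn / denom


def average_precision(entries: Sequence[tuple[float, bool]], n_positives: int,
                      method: str = "rectangle") -> float:
    """AP of a confidence-ranked detection list.

    ``entries`` are (confidence, is_true_positive); ``n_positives`` is the
    total ground-truth positive count.  ``rectangle`` is the standard
    non-interpolated sum of Precision(n)/n_positives over TP ranks;
    ``trapezoid`` integrates the precision-recall polyline instead.
    """
    if n_positives < 1:
        raise ValueError("average precision needs >= 1 ground-truth positive")
    ranked = sorted(entries, key=lambda e: -e[0])
    if method == "rectangle":
        ap, tp_seen = 0.0, 0
        for n, (_, is_tp) in enumerate(ranked, start=1):
            if is_tp:
                tp_seen += 1
                ap += tp_seen / n
        return ap / n_positives
    if method == "trapezoid":
        recall_prev, prec_prev, tp_seen, ap = 0.0, 1.0, 0, 0.0
        for n, (_, is_tp) in enumerate(ranked, start=1):
            if is_tp:
                tp_seen += 1
            recall, prec = tp_seen / n_positives, tp_seen / n
            ap += (recall - recall_prev) * (prec + prec_prev) / 2.0
            recall_prev, prec_prev = recall, prec
        return ap
    raise ValueError(f"unknown AP method {method!r}")


def mean_average_precision(aps: Mapping[int, float] | Sequence[float]) -> float:
    values = list(aps.values()) if isinstance(aps, Mapping) else list(aps)
    values = [v for v in values if v is not None]
    if not values:
        raise UndefinedMetricError("no class has a defined AP")
    return float(np.mean(values))


def intersect_model_outputs(record_lists: Sequence[Sequence[DetectionRecord]]
                            ) -> list[DetectionRecord]:
    """Consensus of >= 2 models: keep (sample, label) present in every list with
    pairwise-overlapping intervals; DI = interval intersection, confidence = mean.

    For 1-D intervals pairwise overlap implies a common intersection, so the
    test reduces to max(sRT) <= min(eRT).
    """
    if len(record_lists) < 2:
        raise ValueError("need at least two record lists to intersect")
    keyed: list[dict[tuple[str, int], DetectionRecord]] = []
    for recs in record_lists:
        d: dict[tuple[str, int], DetectionRecord] = {}
        for r in recs:
            key = (r.sample_id, r.label)
            if key in d:
                raise ValidationError(f"duplicate detection for {key}")
            d[key] = r
        keyed.append(d)
    common = set(keyed[0])
    for d in keyed[1:]:
        common &= set(d)
    out = []
    for key in sorted(common):
        group = [d[key] for d in keyed]
        lo, hi = max(r.sRT for r in group), min(r.eRT for r in group)
        if lo > hi:
            continue
        out.append(DetectionRecord(sample_id=key[0], label=key[1], sRT=lo, eRT=hi,
                                   confidence=float(np.mean([r.confidence
                                                             for r in group]))))
    return out


# ---------------------------------------------------------------------------
# cohort-level report


@dataclass
class EvalReport:
    """Aggregate counts and metrics over all evaluated samples."""

    counts: dict[str, int]
    sensitivity_expert: float | None
    sensitivity_corrected: float | None
    specificity_expert: float | None
    specificity_corrected: float | None
    ap_expert: dict[int, float]
    ap_corrected: dict[int, float]
    map_expert: float | None
    map_corrected: float | None

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "sensitivity": {"expert": self.sensitivity_expert,
                            "corrected": self.sensitivity_corrected},
            "specificity": {"expert": self.specificity_expert,
                            "corrected": self.specificity_corrected},
            "ap": {"expert": {str(k): v for k, v in self.ap_expert.items()},
                   "corrected": {str(k): v for k, v in self.ap_corrected.items()}},
            "map": {"expert": self.map_expert, "corrected": self.map_corrected},
        }


def _safe(fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except UndefinedMetricError:
        return None


def evaluate_cohort(records_by_sample: Mapping[str, Sequence[DetectionRecord]],
                    prerule_by_sample: Mapping[str, Sequence[Detection]],
                    annotations: Sequence[VocAnnotation],
                    era_of_sample: Mapping[str, int],
                    n_target_classes: int,
                    rt_ranges: Mapping[tuple[int, int], RTRange] | None = None,
                    range_annotations: Sequence[VocAnnotation] | None = None,
                    ) -> EvalReport:
    """Run both evaluation schemes over all samples and assemble the report.

    ``annotations`` is the ground truth of the evaluated samples;
    ``range_annotations`` (default: same) feeds the per-era RT ranges.
    """
    if rt_ranges is None:
        src = annotations if range_annotations is None else range_annotations
        rt_ranges = compute_rt_ranges(src, era_of_sample)

    ann_by_sample: dict[str, list[VocAnnotation]] = {}
    for a in annotations:
        ann_by_sample.setdefault(a.sample_id, []).append(a)

    counts = {k: 0 for k in ("tp", "ttp", "fp", "ttn", "fn",
                             "tn", "fp_star", "ttp_star",
                             "tp_presence", "fn_presence")}
    # per-class AP inputs
    det_flags: dict[int, list[tuple[float, bool, bool]]] = {}  # conf, tp, tp-or-ttp
    n_pos_expert: dict[int, int] = {}
    n_pos_corrected: dict[int, int] = {}

    for sid, records in records_by_sample.items():
        era = era_of_sample[sid]
        ranges_era = {lab: rng for (lab, e), rng in rt_ranges.items() if e == era}
        anns = ann_by_sample.get(sid, [])
        outcome = reclassify_tentatives(prerule_by_sample.get(sid, ()),
                                        match_detections(records, anns),
                                        ranges_era)
        counts["tp"] += len(outcome.tp)
        counts["ttp"] += len(outcome.ttp)
        counts["fp"] += len(outcome.fp)
        counts["ttn"] += len(outcome.ttn)
        counts["fn"] += len(outcome.fn)

        tp_recs = {id(r) for r, _ in outcome.tp}
        ttp_recs = {id(r) for r in outcome.ttp}
        for r in records:
            is_tp = id(r) in tp_recs
            is_ttp = id(r) in ttp_recs
            det_flags.setdefault(r.label, []).append(
                (r.confidence, is_tp, is_tp or is_ttp))
        for a in anns:
            n_pos_expert[a.label] = n_pos_expert.get(a.label, 0) + 1
        for r, _ in outcome.tp:
            n_pos_corrected[r.label] = n_pos_corrected.get(r.label, 0) + 1
        for r in outcome.ttp:
            n_pos_corrected[r.label] = n_pos_corrected.get(r.label, 0) + 1
        for a in outcome.fn:
            n_pos_corrected[a.label] = n_pos_corrected.get(a.label, 0) + 1

        presence = presence_confusion(records, anns, ranges_era, n_target_classes)
        for cat in presence.values():
            key = {"TN": "tn", "FP*": "fp_star", "TTP*": "ttp_star",
                   "TP": "tp_presence", "FN": "fn_presence"}[cat]
            counts[key] += 1

    ap_expert: dict[int, float] = {}
    ap_corrected: dict[int, float] = {}
    for j in range(1, n_target_classes + 1):
        entries = det_flags.get(j, [])
        if n_pos_expert.get(j, 0) >= 1:
            ap_expert[j] = average_precision([(c, tp) for c, tp, _ in entries],
                                             n_pos_expert[j])
        else:
            logger.warning("class %d has no ground-truth positives; AP skipped", j)
        if n_pos_corrected.get(j, 0) >= 1:
            ap_corrected[j] = average_precision([(c, x) for c, _, x in entries],
                                                n_pos_corrected[j])

    return EvalReport(
        counts=counts,
        sensitivity_expert=_safe(sensitivity, counts, "expert"),
        sensitivity_corrected=_safe(sensitivity, counts, "corrected"),
        specificity_expert=_safe(specificity, counts, "expert"),
        specificity_corrected=_safe(specificity, counts, "corrected"),
        ap_expert=ap_expert,
        ap_corrected=ap_corrected,
        map_expert=_safe(mean_average_precision, ap_expert),
        map_corrected=_safe(mean_average_precision, ap_corrected),
    )
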