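"""Independent brute-force reference implementations used as test oracles.

These deliberately trade efficiency for literalness: plain loops and
exhaustive enumeration, sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_runs(labels):
    """Maximal constant runs by a left-to-right scan: (label, start, length)."""
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((int(labels[i]), i, j - i))
        i = j
    return runs


def brute_duration(labels, gamma):
    """Detections as (label, start, length) runs with label > 0 and length >= gamma."""
    return [(lab, s, n) for lab, s, n in brute_runs(labels)
            if lab > 0 and n >= gamma]


def brute_confidence(confidences, start, length, gamma):
    """Max over every length-gamma contiguous sub-run of its plain mean."""
    best = -1.0
    for i in range(start, start + length - gamma + 1):
        best = max(best, sum(confidences[i:i + gamma]) / gamma)
    return best


def brute_order(detections):
    """Literal evaluation of the order-rule set subtraction.

    ``detections``: sequence of objects with .label and .sRT.  A detection
    d_f is removed when some chain d_f < d_1 < d_2 < d_3 exists with three
    distinct labels all < f, or a chain d_1 < d_2 < d_3 < d_f with three
    distinct labels all > f, where d < d' means sRT(d) <= sRT(d') for
    distinct detections.
    """
    def lt(a, b):
        return a is not b and a.sRT <= b.sRT

    kept = []
    for f in detections:
        removed = False
        for trio in itertools.combinations([d for d in detections if d is not f], 3):
            labels = {d.label for d in trio}
            if len(labels) != 3:
                continue
            chain = sorted(trio, key=lambda d: d.sRT)
            if not (lt(chain[0], chain[1]) and lt(chain[1], chain[2])):
                continue
            if all(l < f.label for l in labels) and lt(f, chain[0]):
                removed = True
                break
            if all(l > f.label for l in labels) and lt(chain[2], f):
                removed = True
                break
        if not removed:
            kept.append(f)
    return kept


def brute_uniqueness(detections):
    """Keep per label the max-confidence detection; ties -> smallest sRT."""
    out = []
    for lab in sorted({d.label for d in detections}):
        group = [d for d in detections if d.label == lab]
        best = group[0]
        for d in group[1:]:
            if (d.confidence, -d.sRT) > (best.confidence, -best.sRT):
                best = d
        out.append(best)
    return out


def ap_step_integral(entries, n_positives, grid_check=False):
    """AP as the exact integral of the right-continuous precision-of-recall
    step function, built pointwise from the ranked list."""
    ranked = sorted(entries, key=lambda e: -e[0])
    recalls, precisions = [], []
    tp = 0
    for n, (_, is_tp) in enumerate(ranked, 1):
        if is_tp:
            tp += 1
            recalls.append(tp / n_positives)
            precisions.append(tp / n)
    total = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, precisions):
        total += (r - prev_r) * p
        prev_r = r
    return total


def mc_intersect_probability(range_lo, range_hi, interval_len, R, n_draws, seed):
    """Monte-Carlo placement of a random interval of fixed length in [0, R]."""
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, R - interval_len, size=n_draws)
    hits = (starts <= range_hi) & (range_lo <= starts + interval_len)
    p = hits.mean()
    se = np.sqrt(p * (1 - p) / n_draws)
    return p, se
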