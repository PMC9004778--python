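"""Stage-2 phase A: slide the trained classifier across a whole sample.

Every start index i in [0, R - delta] yields one window (stride 1 — the
duration rule's run-length semantics depend on it).  Each window is min-max
normalised with the same per-window rule used in training, then classified;
the outputs are the label sequence L_A and confidence sequence T_A of length
N = R - delta + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ScanError
from .io import AbundanceMatrix
from .nn.models import CNN, TrainedModel


@dataclass
class ScanResult:
    """Phase-A output for one sample: parallel label and confidence sequences."""

    sample_id: str
    labels: np.ndarray        # L_A, ints, length N
    confidences: np.ndarray   # T_A, floats in [1/(J+1), 1], length N
    delta: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.confidences = np.asarray(self.confidences, dtype=float)
        if self.labels.shape != self.confidences.shape:
            raise ValueError("labels and confidences must have equal length")

    @property
    def n_windows(self) -> int:
        return len(self.labels)


def normalize_windows(windows: np.ndarray) -> np.ndarray:
    """Per-window min-max scaling of a (B, delta, C) stack; constant -> zeros."""
    w = windows.astype(np.float32, copy=True)
    lo = w.min(axis=(1, 2), keepdims=True)
    hi = w.max(axis=(1, 2), keepdims=True)
    rng = hi - lo
    rng[rng == 0] = 1.0
    w -= lo
    w /= rng
    return w


def scan_sample(model: TrainedModel | CNN, m: AbundanceMatrix, delta: int,
                batch_size: int = 256) -> ScanResult:
    """Classify every stride-1 window of the sample; N = R - delta + 1 outputs."""
    net = model.model if isinstance(model, TrainedModel) else model
    R = m.n_scans
    if R < delta:
        raise ScanError(f"matrix with {R} rows is shorter than the window ({delta})")
    n = R - delta + 1
    view = sliding_window_view(m.values, delta, axis=0)   # (N, C, delta)
    labels = np.empty(n, dtype=int)
    confs = np.empty(n, dtype=float)
    for i in range(0, n, batch_size):
        batch = view[i:i + batch_size].transpose(0, 2, 1)
        probs = net.predict_proba(normalize_windows(batch))
        labels[i:i + batch_size] = probs.argmax(axis=1)
        confs[i:i + batch_size] = probs.max(axis=1)
    return ScanResult(sample_id=m.sample_id, labels=labels, confidences=confs,
                      delta=delta)


def save_scan(scan: ScanResult, path) -> None:
    import csv
    import json
    from pathlib import Path
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["window_start", "label", "confidence"])
        for i, (lab, t) in enumerate(zip(scan.labels, scan.confidences)):
            w.writerow([i, int(lab), repr(float(t))])
    Path(str(path) + ".meta.json").write_text(
        json.dumps({"sample_id": scan.sample_id, "delta": scan.delta}))


def load_scan(path) -> ScanResult:
    import csv
    import json
    from pathlib import Path
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    labels, confs = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels.append(int(row["label"]))
            confs.append(float(row["confidence"]))
    return ScanResult(sample_id=meta["sample_id"], labels=np.array(labels),
                      confidences=np.array(confs), delta=int(meta["delta"]))
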