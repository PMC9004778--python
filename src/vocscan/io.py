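"""Data model and I/O for GC-MS abundance matrices, annotations and detections.

A GC-MS run yields a dense abundance matrix: rows are retention-time (RT)
scans acquired at a fixed rate (~6.25 Hz on the instrument this package
models), columns are unit-resolution m/z channels (40-450, i.e. 411
channels).  All RT arithmetic inside the pipeline is in row-index units;
seconds only appear at presentation time through :meth:`AbundanceMatrix.rt_of`.

Native formats are deliberately simple and open:

* matrix: ``.npy`` or a delimited text table, with a JSON metadata sidecar;
* annotations: CSV with header ``sample_id,label,startRT,peakRT,endRT``;
* detections: CSV with header ``sample_id,label,sRT,eRT,confidence``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, MetadataError, ValidationError

SAMPLE_KINDS = ("breath", "environmental")

_META_KEYS = ("sample_id", "participant_id", "scan_rate_hz", "mz_start",
              "column_era", "sample_kind")


@dataclass
class AbundanceMatrix:
    """One raw GC-MS sample: an R x C nonnegative intensity matrix plus metadata."""

    values: np.ndarray
    sample_id: str
    participant_id: str
    scan_rate_hz: float = 6.25
    mz_start: int = 40
    column_era: int = 1
    sample_kind: str = "breath"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("abundance matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("abundance matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("abundance matrix contains negative intensities")
        if self.scan_rate_hz <= 0:
            raise ValidationError("scan_rate_hz must be positive")
        if self.column_era not in (1, 2):
            raise ValidationError(f"column_era must be 1 or 2, got {self.column_era}")
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValidationError(f"sample_kind must be one of {SAMPLE_KINDS}")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def rt_of(self, i: int) -> float:
        """Retention time in seconds of scan row ``i`` (linear in the index)."""
        if not 0 <= i < self.n_scans:
            raise IndexError(f"row {i} out of range [0, {self.n_scans})")
        return i / self.scan_rate_hz


def rt_of(m: AbundanceMatrix, i: int) -> float:
    """Module-level alias for :meth:`AbundanceMatrix.rt_of`."""
    return m.rt_of(i)


@dataclass(frozen=True)
class VocAnnotation:
    """Ground-truth location of one VOC occurrence in one sample.

    ``startRT``/``peakRT``/``endRT`` are row indices; the elution interval
    [startRT, endRT] is closed (both rows contain the compound).
    """

    sample_id: str
    label: int
    startRT: int
    peakRT: int
    endRT: int

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValidationError("annotation label must be >= 1 (0 is the negative class)")
        if not 0 <= self.startRT <= self.peakRT <= self.endRT:
            raise ValidationError(
                f"need 0 <= startRT <= peakRT <= endRT, got "
                f"({self.startRT}, {self.peakRT}, {self.endRT})")

    @property
    def span(self) -> int:
        """Elution duration as inclusive row count."""
        return self.endRT - self.startRT + 1


@dataclass(frozen=True)
class VocClassTable:
    """Ordered class labels; position in the list is expected elution order.

    Label 0 is reserved for the negative (no target VOC) class.
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if labels != list(range(len(labels))):
            raise ValidationError("labels must be contiguous 0..J in order")
        if not labels or self.entries[0][0] != 0:
            raise ValidationError("label 0 (negative class) must be first")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "VocClassTable":
        return cls(tuple((i, n) for i, n in enumerate(["negative", *names])))

    @property
    def n_classes(self) -> int:
        """Number of classes including the negative class (J + 1)."""
        return len(self.entries)

    def name_of(self, label: int) -> str:
        return self.entries[label][1]


@dataclass(frozen=True)
class DetectionRecord:
    """Final phase-B output: [label, sRT, eRT, confidence] for one sample."""

    sample_id: str
    label: int
    sRT: int
    eRT: int
    confidence: float

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValidationError("detection label must be >= 1")
        if self.sRT > self.eRT:
            raise ValidationError("sRT must be <= eRT")


# ---------------------------------------------------------------------------
# matrix I/O

def write_sample(m: AbundanceMatrix, path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix (``.npy`` or delimited text by extension) + JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, m.values)
    else:
        np.savetxt(path, m.values, delimiter=",")
    meta = {"sample_id": m.sample_id, "participant_id": m.participant_id,
            "scan_rate_hz": m.scan_rate_hz, "mz_start": m.mz_start,
            "column_era": m.column_era, "sample_kind": m.sample_kind}
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def load_sample(path: str | Path, meta_path: str | Path) -> AbundanceMatrix:
    """Load a matrix file and its metadata sidecar into an AbundanceMatrix."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as e:
            raise FormatError(f"{path} is not a rectangular numeric table: {e}") from e
    try:
        meta = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as e:
        raise MetadataError(f"{meta_path} is not valid JSON: {e}") from e
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise MetadataError(f"{meta_path} missing keys: {missing}")
    return AbundanceMatrix(values=values, **{k: meta[k] for k in _META_KEYS})


# ---------------------------------------------------------------------------
# annotation I/O

_ANN_HEADER = ["sample_id", "label", "startRT", "peakRT", "endRT"]


def save_annotations(annotations: Iterable[VocAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ANN_HEADER)
        for a in annotations:
            w.writerow([a.sample_id, a.label, a.startRT, a.peakRT, a.endRT])


def load_annotations(path: str | Path) -> list[VocAnnotation]:
    out: list[VocAnnotation] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames != _ANN_HEADER:
            raise FormatError(f"unexpected annotation header {r.fieldnames}")
        for row in r:
            out.append(VocAnnotation(sample_id=row["sample_id"], label=int(row["label"]),
                                     startRT=int(row["startRT"]), peakRT=int(row["peakRT"]),
                                     endRT=int(row["endRT"])))
    return out


# ---------------------------------------------------------------------------
# detection I/O

_DET_HEADER = ["sample_id", "label", "sRT", "eRT", "confidence"]


def save_detections(records: Iterable[DetectionRecord], path: str | Path) -> None:
    """Write detection records; confidence at full repr precision for round-trips."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_DET_HEADER)
        for d in records:
            w.writerow([d.sample_id, d.label, d.sRT, d.eRT, repr(float(d.confidence))])


def load_detections(path: str | Path) -> list[DetectionRecord]:
    out: list[DetectionRecord] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames != _DET_HEADER:
            raise FormatError(f"unexpected detection header {r.fieldnames}")
        for row in r:
            out.append(DetectionRecord(sample_id=row["sample_id"], label=int(row["label"]),
                                       sRT=int(row["sRT"]), eRT=int(row["eRT"]),
                                       confidence=float(row["confidence"])))
    return out
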