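# Methods

This note records the models, parameter choices and numerical conventions
behind `vocscan`, and what the synthetic experiments do and do not show.

## Data model and conventions

A sample is a dense abundance matrix (rows = RT scans, columns = m/z
channels) with nonnegative intensities. All positions are handled in
row-index units; seconds appear only at presentation time via the linear
map `rt = i / scan_rate_hz` (default 6.25 Hz). Annotation intervals
`[startRT, endRT]` are closed and 0-based, so the inclusive elution span is
`endRT − startRT + 1` rows. The window size is

```
δ = max_span_inclusive + margin   (rounded up to even),
```

with `margin = 19` so that the 20 translation shifts (−9…+10) of a
maximal-span peak all keep the full elution inside the window; a ~61-row
maximum elution gives the canonical δ = 80. The duration-rule threshold
γ = 20 is the same margin seen from the scanner's side: a full peak is
visible in at least `δ − span + 1 ≥ 20` consecutive windows.

## Synthetic cohort generator

The generator emulates a targeted breathomics study so the pipeline can be
validated against known truth:

* **Ion patterns** — per class, a sparse vector over m/z (default 8 ions)
  with the base peak at 1 and the rest U(0.05, 0.9); patterns are fixed
  across occurrences, which is the invariance the classifier exploits.
* **Elution** — Gaussian envelope in scan index. The drawn duration `d`
  (N(30, 5²) scans by default, clipped to [5, mean+3sd]; the library
  invariant keeps mean+3sd ≤ 61) sets the envelope width via
  `σ = d / (2√(2 ln 100))`, so the 1%-of-maximum cut-off used to record
  startRT/endRT reproduces `d` as the annotated span. peakRT is the
  envelope argmax. No tailing is modelled.
* **Concentrations** — log-uniform per occurrence; regular classes
  10^3.5–10^5, designated low-concentration classes 10^1–10^2 (counts),
  giving the ≥10⁴ library dynamic range typical of breath panels, with the
  low classes near the noise floor as real trace compounds are.
* **Confounders** — an overlap pair (consecutive labels) shares a stated
  number of its 5 strongest ions and is forced to co-elute (centre offset
  0.3–0.8 of an elution width); per-sample RT jitter N(0, 4²) scans; a
  constant era shift (+30 scans by default) for participants measured
  after the column change (first half of participants era 1, rest era 2).
* **Noise** — constant baseline (10) plus i.i.d. half-normal noise
  (|N(0, 1)|), keeping intensities nonnegative without a full shot-noise
  model. With noise and baseline at 0 the matrix is exactly the sum of the
  planted outer-product peaks (tested).
* **Cohort structure** — per participant, a fixed number of breath samples
  plus environmental samples that contain only a configurable subset of
  classes (default: every third label) at low concentration. Class
  presence per breath sample is Bernoulli(0.9).

Not emulated: peak tailing and column bleed, mass-calibration drift,
correlated (shot) noise, within-run RT drift, and spectra truncated by
detection limits. Passing the synthetic recovery experiment therefore
shows that the pipeline's machinery — extraction, augmentation, training,
scanning and the rules — is correct and recovers planted truth under
realistic geometry, not that any fixed accuracy carries over to clinical
matrices.

## Augmentation

Translation re-extracts the window at the 20 shifted starts; shifts whose
window leaves the matrix are dropped with a warning. The intensity
multiplier `G_x = exp(−½((x−μ)/σ)²)·r + 1` applies strictly inside
(startRT, endRT) with `r ~ U(0, 0.1)` drawn fresh per variant; boundary
rows are untouched, so background is bit-identical and `1 ≤ G_x ≤ 1+r`.
The Gaussian's width is an operator property, not a datum: σ =
(endRT − startRT)/6, so ±3σ spans the elution interval and the modulation
tapers to ≈1 at its edges, consistent with leaving background unchanged.
Negative-class windows have no elution interval; they are translated like
any window and their "intensity variants" are identity copies, preserving
the 20×5 = 100 bookkeeping. Every emitted window is min–max normalised to
[0, 1] per data point (a constant window maps to zeros); normalisation is
idempotent.

## CNN families and the 1D-filter adaptation

Implemented directly on numpy (float32, im2col + GEMM convolutions,
hand-written backward passes verified against float64 central finite
differences; Adam optimiser, softmax cross-entropy). In 1D mode every
kernel is 3×1 and every pooling 2×1: the network never mixes adjacent m/z
channels, matching the physics — intensities correlate along RT as a peak
elutes, while neighbouring ion channels are nearly independent. 2D mode
(3×3 kernels, 2×2 pooling) is provided for comparison.

* `vgg_like` (depth 4/6/8 = conv layers + final FC): conv widths
  32-32-64-64-128-128-256 truncated to depth−1, max-pool after every
  second conv. Widths are configurable; the desk-scale experiments use
  (8, 8, 16).
* `resnet`: initial conv, then residual conv pairs (1×1 projection on
  width change), pooling between stages.
* `densenet`: three densely-connected blocks (each layer concatenates its
  `growth` new channels), 1×1-conv + pool transitions.

**Classifier head.** After the conv stack the features are averaged over
RT only and flattened across (filters × m/z) into the softmax layer. A
global average over both axes is attractive for parameter count but is
information-destroying in 1D mode: since 1D convolutions never move
information across m/z, averaging over m/z collapses every compound to the
same temporal-profile statistics and the classes become indistinguishable
by construction (empirically, training plateaus at the positive/negative
split). Averaging over RT alone keeps the per-channel evidence — which
ion channels contain a peak — which is exactly what identifies a compound;
it is also the role the flatten+FC head plays in the classical VGG
design. The head's weight count (filters × C × classes) is modest at all
scales used here.

Training defaults: Adam at 1e-3, batch 64, fixed epoch budget; an optional
validation split (`val_fraction > 0`) enables early stopping on validation
accuracy with patience 5 and restores the best parameters. Training is
deterministic for a fixed seed (single-threaded numpy). Cross-validation
splits at participant level (`GroupKFold`), asserting on every fold that
no participant appears on both sides.

## Scanner and detection rules

Scanning is stride 1 over all `N = R − δ + 1` starts — run-length
semantics of the duration rule depend on it — with the same per-window
min–max normalisation as training. Argmax ties break toward the lowest
class index.

* **Duration**: maximal constant-label runs, label > 0, length ≥ γ.
* **Detection interval**: each window is located at its middle row, so
  `DI = [l + δ/2, l + n − 1 + δ/2]`; its length equals the run length.
* **Confidence**: maximum of the length-γ moving average of `T_A` within
  the run (computed before order/uniqueness; it depends only on `T_A`).
* **Order**: evaluated in a single pass against the original detection
  set. A detection with label f is removed if three detections with three
  *distinct* labels all smaller than f start at-or-after it, or three
  distinct labels all larger start at-or-before it. The order by start RT
  is non-strict; equal-start detections witness each other, and the rule
  is not iterated to a fixed point.
* **Uniqueness**: per label, the maximum-confidence detection survives;
  ties break toward the earlier start.

All four rules are equivalence-tested against independent brute-force
implementations on 1000+ segment-structured random sequences (lengths
100–2000, 5–32 classes).

## Evaluation

Scheme 1 (localisation + classification): a detection is TP iff its label
matches an annotation of the sample and `DI` overlaps the annotated
interval — interval overlap is the weakest defensible reading of "matching
RT position" and the package's default. Tentative reclassification
(FP → TTP when any same-class detection from the *pre-order,
pre-uniqueness* set intersects the class's per-era RT range; FN → TTN when
its class has a TTP in the same sample) only moves items between
categories (count conservation is property-tested). The plausibility bound
`P(I ∩ RTrange ≠ ∅) = (|RTrange| + |I|)/(R − |I|)` uses index-difference
lengths and is validated against a Monte-Carlo placement oracle; `P_max`
takes the maxima over ranges and detection intervals.

Scheme 2 (presence): per (sample, class), TN when absent from both sides;
system-only detections become TTP* inside the class range, else FP*.

Benchmarks: expert — sensitivity `TP/(TP+FN+TTN)`, specificity
`TN/(TN+FP*+TTP*)`; system-corrected — `(TP+TTP)/(TP+TTP+FN)` and
`TN/(TN+FP*)`.

AP uses the standard non-interpolated rectangle sum over the
confidence-ranked list (a trapezoid variant is available behind a flag and
oracle-compared); recall denominators are per-benchmark (expert: all
annotations; corrected: TP+TTP+FN per class). mAP averages classes with at
least one ground-truth positive. Model intersection keeps (sample, label)
pairs detected by every model with pairwise-overlapping intervals —
equivalent in 1-D to `max sRT ≤ min eRT` — with the intersected interval
and mean confidence.

## Desk-scale reference experiment

`vocscan.presets.recovery_benchmark_config` fixes the package's standard
end-to-end experiment: 10 classes (one overlap pair sharing 3 top ions,
one low-concentration class), 6 participants × 3 breath samples split 12
training / 6 held-out at participant level, matrices of 4000 × 128,
δ from the training annotations (≈60), depth-4 1D VGG-like with widths
(8, 8, 16), translation-only augmentation, 12 epochs. These sizes keep a
full run to minutes on a single CPU while exercising every mechanism,
including era-split RT ranges and the co-elution/low-concentration
confounders; translation-only augmentation is used at this scale because
the intensity variants contribute little separability when patterns are
exact and concentration is already log-uniform across occurrences.

## Numerical and degenerate-case conventions

* Positive windows that would cross a matrix edge are skipped, never
  padded (padding would fabricate spectra); edge translation shifts are
  dropped with a warning and the counts reported.
* μ uses floor division for odd `startRT + endRT`.
* Negative-window eligibility is strict: zero intersection with any
  annotated interval.
* Negatives are allocated across samples proportionally to each sample's
  count of eligible start positions (largest-remainder rounding, capped at
  availability).
* A constant window min–max-normalises to all zeros.
* Scanning a matrix with `R < δ` is an error; `R = δ` yields one window.
* Metrics with zero denominators raise an undefined-metric error rather
  than returning 0; the cohort report stores them as nulls.

## Known limitations

* The CNN stack is CPU-bound numpy; paper-scale inputs (22500 × 411,
  hundreds of samples) are supported by the data structures but training
  at that scale is impractical here — the families are faithful in
  structure, not replicas of any particular large configuration.
* The generator's Gaussian, tail-free peaks and i.i.d. noise make the
  synthetic task easier than clinical data; reported synthetic metrics are
  upper bounds on mechanism quality, not clinical performance claims.
* Compound abundances are not quantified — the output is presence, RT
  interval and confidence per compound.
* Retention-index conversion and vendor file formats are out of scope;
  inputs are dense matrices with a JSON metadata sidecar.
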