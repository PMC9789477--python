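# Methods

## The model

The pipeline assumes a single subject walking straight toward a static
front-facing camera, turning, and walking back.  The apparent silhouette
height in pixels is then a monotone proxy for proximity, modulated by gait:
the bounding box is constant while the legs are adjacent (mid-stance,
mid-swing) and steps up when they spread (terminal stance, terminal swing).
The height signal of a walk is therefore a noisy staircase rising to a
maximum (closest approach), a dwell during the turn, and a descent.

Processing stages are strictly ordered and stage-checked:
`raw → face_scaled → normalized → smoothed → quantized`.

**Face scaling.** Dividing silhouette height by face height removes
inter-subject stature differences (face height is approximately
proportional to body height).  The default policy divides by *one constant
per recording* — the median of detected face heights.  Dividing by the
*concurrent* per-frame face height would be self-defeating: a detected face
scales with camera distance exactly like the silhouette does, so the
per-frame ratio is nearly constant and the approach signal cancels.  A
per-frame policy (`fh_policy="frame_or_median"`) is kept for detectors
whose output does not track distance.  Note that after min-max
normalization a constant scalar division has no numerical effect; the
scaling matters when comparing or thresholding unnormalized signals and
makes the pipeline provably scale-invariant (property-tested).

**Normalization** (x−min)/(max−min) guarantees min 0 / max 1 exactly at the
`normalized` stage.  Later stages only guarantee values in [0, 1]: a
centered moving average necessarily contracts the extremes, so re-asserting
exact bounds after smoothing would be wrong.

**Smoothing** is a centered 5-frame moving average (0.2 s at 25 fps,
matching the quantization granularity) with shrinking windows at the edges.
The window is configurable.

**Quantization** maps consecutive 5-frame partitions to their uniform mean
(the centroid of the partition's points), yielding a plateau signal; the
tail partition may be shorter.  This is the fixed-partition reading of
Lloyd quantization: each partition of points is represented by one
average-centroid.  An iterative Lloyd–Max codebook (few discrete amplitude
levels) is a possible alternative reading; it was not adopted because a
monotone forward walk spread over a handful of amplitude levels would merge
consecutive steps and destroy stride timing resolution.

**Splitting** happens at the first frame attaining the global maximum of
the normalized signal.  Splitting is performed before smoothing/quantizing
the forward segment so that quantization partitions are aligned with the
forward walk's first frame; event timing therefore does not depend on how
much backward walk was recorded.

## Gait events and stride timing

On the quantized forward walk, a gait event is a partition plateau whose
increment over the previous plateau (i) exceeds `min_rise` (default 0.01
normalized units) and (ii) is a *local maximum* of the increment sequence —
the locally steepest point of amplitude increase.  Two practical failure
modes dictate this rule:

* a single physical rise whose ramp straddles a partition boundary produces
  two or three consecutive increasing plateaus; emitting an event per
  increasing plateau would double-count nearly every step and halve the
  measured stride time;
* with any detection noise, about half of all junctions between equal-height
  plateaus are "strictly increasing"; `min_rise` suppresses these (the
  post-smoothing plateau noise is well below 0.01 for realistic ~1 px
  bounding-box jitter, while true step rises are several times larger).

Inter-event intervals alternate stance, swing, stance, … and consecutive
(stance, swing) pairs form strides (trailing unpaired interval dropped);
`S_avg` is the mean stride time.  Event timestamps are quantized to the
0.2 s partition grid, so individual stride times carry ±0.2 s jitter; the
mean over a walk telescopes most of it away.  The simulator emits two rises
per stride, consistent with the terminal-stance/terminal-swing mechanism,
which is what makes `S_avg ≈ 1/cadence` hold.  Cadences above ~1.2
strides/s approach the resolution limit of 5-frame partitions at 25 fps
(a step every ≤ 2 partitions); recovery degrades gracefully but accuracy
there is partition-limited.

## Signal features

* **DFA `alpha`** — integrate the mean-subtracted signal, detrend
  non-overlapping boxes of size l = 5, 10, …, n/4 by their least-squares
  line, pool the RMS residual per size, and fit the log-log slope (at least
  4 box sizes required).  Verified against theory (white ≈ 0.5, 1/f ≈ 1,
  Brownian ≈ 1.5) and against an independent reference implementation.
* **Entropy `E`** — −Σ x·log₂x over the normalized amplitudes as printed,
  with 0·log₂0 := 0.  This is a sum over samples, not a probability
  distribution, so `E` grows with recording length — which is itself
  severity-relevant (impaired walks are longer).
* **Spectral centroids / `A_delta_C`** — per 5-sample box, the magnitude
  spectrum over non-negative DFT frequencies i·fps/5 gives a centroid
  C = Σf·x / Σx; `A_delta_C` is the mean of consecutive centroid
  differences with divisor N (the number of centroids).  The signed form is
  the printed formula and the default; note that the signed sum telescopes
  to (C_N − C_1)/N, so it is near zero on stationary signals — this is why
  it is weakly discriminative on simulated walks.  The absolute-difference
  variant (`abs_centroid_diff=True`) measures centroid variability proper.
* **`T`** — |argmax − argmin| / fps on first occurrences, i.e. the
  valley-to-peak traversal time; effectively the forward-walk duration.

`alpha`, `E`, `A_delta_C` and `T` are computed on the normalized full walk
by default (`feature_segment="forward"` restricts them to the approach);
events and `S_avg` are always computed on the forward segment.

## Classifier

Features are standardized (mean/scale from the training split only — the
five features mix seconds, Hz and dimensionless quantities, and the PUK
kernel is distance-based), then three binary soft-margin SVMs (C = 1
default) are fitted on the precomputed PUK Gram matrix, one per severity
level versus the rest.  Prediction is the argmax of the three decision
scores, ties toward the lower level.  Stratified 10-fold cross-validation
partitions the data so each sample is tested exactly once; reported are
per-fold accuracy (and its mean), the pooled confusion matrix, per-class
TPR, and per-class ROC/AUC from pooled out-of-fold scores with the macro
AUC as the headline number.  Fold assignment is seeded and recorded in the
report.

## The simulator

`synthetic.GaitProfile` parameters (units): cadence (strides/s), per-stride
amplitude (pre-normalization units; only ratios survive normalization),
multiplicative cadence/amplitude jitters, festination rate (probability per
stride of replacing it with 2–3 quick short rises in ~60% of the stride
period), turn dwell (s), forward duration (s), detection noise SD (fraction
of the total height span; 0.01 ≈ 1 px jitter on a ~120 px span), subject
pixel height and face ratio.  Class defaults encode the qualitative
clinical contrasts — healthy: ~1.0–1.15 strides/s, 5.5–7.5 s approach,
large regular steps; level 1: slower, smaller and more irregular steps,
8–11 s; level 2: slowest, smallest steps, 11–15 s, festination — with
ranges chosen so that classes are separable by construction.

What the simulator does **not** emulate: perspective nonlinearity of the
approach (height is linear in the scripted profile), arm/posture variation,
detector dropouts correlated with pose, camera shake, lighting, or the
clinical overlap between adjacent severity levels.  Passing the end-to-end
classification test therefore demonstrates that the pipeline recovers the
generating structure, not that clinical accuracy would reach the same
level; on real recordings the levels overlap substantially more.

Determinism: every walk is a pure function of (profile, fps, seed); dataset
generation derives per-walk profile and signal seeds from the master seed
and logs signal seeds in the label file.  Rendered silhouette videos
(blocky head/torso/legs figure, head block = face height, fixed ground
line) are byte-deterministic, and the default segmentation detector
recovers the scripted heights exactly up to integer rounding.

## Numerical choices and degenerate inputs

Ties at the height maximum split at the first occurrence.  Constant signals
raise explicit degenerate-signal errors (normalization, DFA, valley-peak).
Zero-magnitude spectra yield centroid 0.  Batch feature extraction never
aborts: a recording failing any stage yields a flagged incomplete vector
that is excluded from training with a logged warning.  Kruskal-Wallis with
all-identical values (tie correction undefined) is reported as H = 0,
p = 1.  The one-sided-walk condition (maximum at the first/last frame) is a
warning, not an error; downstream feature extraction then typically flags
the recording.

## Problem sizes used in tests

The suite runs entirely on simulated data: cohorts of 50 walks per class
for the classification check, 10–20 seeds for recovery/ordering properties,
series of length 2000 for DFA, and a ~6 s rendered video for the tracking
round trip.  These sizes were chosen as the smallest at which the measured
quantities are stable well inside their tolerance bands.
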