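# Methods

This note documents the models behind `sonoflow`: what the synthetic
session generator emulates, how each analysis stage is defined, the
numerical conventions, and what the package's passing tests do and do not
establish about real clinical data.

## The synthetic scanning workload

No public corpus of full-length obstetric scan recordings exists (patient
data governance), so the package is driven by a generator whose defaults
encode a reference second-trimester workload (`sonoflow.reference`): scan
durations of 36.2 ± 11.6 min, a 13-label anatomy vocabulary (12 common
standard-plane labels plus `other`), label time shares led by cardiac
imaging at 21.5%, clip-label prevalences led by thorax–heart at 19.6%,
1409 biometric measurement displays per 272 growth scans, a 4.2%
bioeffect-box gaze-adherence rate, and a five-class part-of-speech token
distribution for sonographer speech (12.7 / 22.2 / 28.0 / 16.0 / 21.1%).

### Scan duration

Truncated normal, mean 36.2 min, SD 11.6 min, resampled into [10, 90] min.
Truncation is asymmetric (the lower bound is 2.3 SD below the mean, the
upper 4.6 SD above), which shifts the model mean to ≈ 36.6 min; this ~0.4
min bias is inherent to bounding an asymmetric normal and is well inside
the sampling error of a 341-scan mean (SE ≈ 0.63 min).

### Anatomy timeline (semi-Markov)

Each scan is a sequence of dwell segments. A segment's label is drawn with
probability proportional to `share / mean_dwell` (so long-run time
fractions equal the configured shares regardless of per-label dwell
means), and its dwell time is gamma-distributed with shape 2 — positive,
right-skewed, two-parameter — and scale set from the per-label mean dwell
(default 20 s for all labels, giving ≈ 110 segments in a typical scan).
The final segment is truncated at the scan end.

Between-scan variability: each scan first perturbs the shares by a
Dirichlet draw with concentration 60. This keeps the invariant that cohort
time fractions converge to the configured shares within 1 percentage point
over a few hundred scans, while giving every scan its own emphasis. The
reference 95% CIs would suggest a somewhat larger spread (concentration
15–30); users studying between-scan variance itself should lower
`share_concentration` accordingly.

### Machine UI stream

One row per video frame (30 fps default): freeze flag, save icon,
measurement display (type + value in mm), thermal index. Freezes occur at
segment level (probability 0.6, in the later part of the segment — the
sonographer freezes when satisfied with an acquisition), last 2–6 s, and
are separated by ≥ 1 s so measurement debouncing can never merge displays
from different acquisitions. Saves (image 0.5, clip 0.1 per freeze) happen
only while frozen. Each planned biometric measurement is hosted by its own
freeze; if the random plan yields too few freezes, extra ones are carved
from the longest unfrozen stretch so planted counts are always exact.
Measurement values are drawn per type (HC ≈ 175 ± 10 mm, AC ≈ 150 ± 12 mm,
FL ≈ 34 ± 3 mm, plausible mid-gestation magnitudes) and rounded to the
0.1 mm shown on the display.

The stream exists in two equivalent forms: the structured table, and
rendered rasters (a 5×7 bitmap font scaled 4×, fixed widget rectangles).
Rendering is a deterministic pixel function of the state, so the raster
channel is exactly recoverable on clean frames; tests assert
raster/structured equivalence and that corrupted glyph cells are refused
(best template score < 0.99) rather than guessed.

### Gaze stream

90 samples/s (a typical remote-tracker rate — a default, not a claim about
any specific device), isotropic Gaussian noise (σ = 12 px) around an
attractor at the image-area centre, 2% invalid samples. Around each
measurement display the attractor moves to the measurement box for 0.8 s
with probability 0.93, emulating the near-universal glance at displayed
values. `plant_fixation` relocates a chosen time window into a named AOI
for controlled experiments.

### IMU stream and ground-truth orientation

The transducer trajectory is scripted: yaw/pitch/roll follow sums of two
sinusoids (amplitudes up to 0.35 rad, 0.05–0.3 Hz; aerospace ZYX
convention, world z up), and translation follows sinusoids of ≈ 1 cm at
0.1–0.8 Hz — slow, smooth movements of a hand-guided probe. Body angular
rates come from the exact Euler kinematics, the accelerometer reads
`R(q)ᵀ(a_world − g)` and the magnetometer `R(q)ᵀ(1,0,0)` (renormalized to
unit length), so all channels are mutually consistent with the stored
ground-truth quaternion and world linear acceleration; in noise-free mode
this consistency is exact to numerical precision. Default sensor noise:
gyro σ = 0.005 rad/s, accel σ = 0.05 m/s², mag σ = 0.01 — enough to make
fusion non-trivial, small enough to be recoverable.

### Speech

Sentences are emitted per timeline segment (probability 0.4) with lengths
1 + Poisson(7), capped at 83 words. Each token first draws a POS tag from
the configured weights, then a word uniformly from that tag's entries in a
~380-word scanning lexicon. Token-level POS fractions therefore converge
to the weights by construction; vocabulary size and sentence-length
statistics are emergent.

### What the generator does **not** emulate

No ultrasound image content (rasters carry only UI glyphs), no saccade
dynamics or smooth pursuit, no gyro bias or magnetometer hard-iron error,
no speaker overlap or disfluencies, no correlation between anatomy and
probe motion. Passing tests demonstrate that the *analysis stages* are
correct against controlled ground truth; they do not validate the stages
against the idiosyncrasies of real recordings.

## Analysis conventions

* **Event timestamps** are `frame_index / frame_rate`, 0-based frames.
* **Measurement displays** fire on value change; a display interrupted
  < 0.5 s that resumes with the same value is one event (debounce).
* **Clips** end at their anchor event (the approach context precedes the
  moment of satisfaction); the anchoring side is a convention, not a
  measured fact. Dedup drops a window overlapping an earlier kept window
  by ≥ 50% of the shorter of the two. Label ties break toward the later
  segment (the content on screen at the anchor).
* **Fixations**: run length is last-minus-first in-AOI timestamp, making
  the ≥ 100 ms rule sampling-rate independent; invalid samples break runs
  (conservative); the ≤ 400 ms merge bound is inclusive. The ±2 s biometry
  audit window is a configurable convention.
* **AHRS**: predict-then-correct — the quaternion is propagated with the
  gyro rate, then moved `gain·dt` along the unit-normalized negative
  gradient of the gravity+magnetic alignment error evaluated at the
  *predicted* attitude (evaluating at the pre-update attitude would bias
  the estimate one sample ahead at high rotation rates). Free fall
  (zero-norm accelerometer) degrades to gyro-only. Initialization is a
  TRIAD construction from the first accelerometer/magnetometer pair.
  Gain 0 is exactly pure gyro integration. Frame alignment is
  nearest-sample (100 Hz against 30 fps: ≤ 5 ms, interpolation
  unnecessary).
* **Smoothing**: 31-frame centered mode filter (ties keep the previous
  output label), then segments shorter than 1 s are absorbed into the
  longer neighbour. Both parameters are package choices.
* **Cohort CIs** are Student-t on per-scan share percentages.
* **Share correlation** is the Pearson coefficient over flattened
  per-scan-per-label share vectors — one defensible reading of comparing
  two labelings' duration profiles; per-label or per-scan variants are
  easily computed from the same tables.
* **Agreement** is compared at clip level. The corruption model replaces a
  label with probability `1 − target` by a uniformly chosen different
  label, so its expected agreement equals the target exactly; the
  nearest-centroid classifier (one-hot centroids, isotropic feature noise,
  lexicographic tie-break) provides an alternative error process whose
  accuracy is calibrated by Monte-Carlo bisection.

## Problem sizes

The acceptance computations use the cohort sizes of the reference
workload: 341 scans for time shares and durations, 20,000 clip labels for
prevalence, 637 scans (27 with planted bioeffect fixations) for the safety
audit, 272 scans carrying 354 + 703 + 352 planted measurement displays for
the biometry count, 28 scans of clips for agreement, and ≥ 10,000 tokens
for speech. Experiments that only count planted events (safety, biometry)
run on shortened scans (30 s and 3 min respectively) since scan length is
immaterial to those counts; orientation-recovery checks use ~1-minute
trajectories, long enough for several full attitude cycles.

## Known limitations

* The truncated-normal duration model cannot reproduce a heavy upper tail
  of very long scans.
* The flat corruption model spreads confusion uniformly; real confusions
  are structured (e.g. labels whose structures co-occur in one image).
* The AHRS recovery tolerances are defined against this generator's
  synthetic ground truth, not against any physical device.
* With a magnetic field parallel to gravity the TRIAD heading is
  unobservable; the implementation falls back to an arbitrary horizontal
  axis (logged, not failed).
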