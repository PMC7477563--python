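# Methods

## Problem and conventions

A pharyngeal-phase VFSS clip of a few seconds contains one (occasionally
more) swallowing reflex lasting 1–13 frames at 15 fps.  The task is to
predict the reflex interval `[t̂_s, t̂_e)` and score it against the
clinician-annotated `[t_s, t_e)`.

All intervals inside the package are **half-open, 0-based**.  With this
convention the *before* window `[t_s − L, t_s)` contains exactly `L` frames
and ends right before the reflex onset, and the *after* window `[t_e,
t_e + L)` starts right at the offset.  Annotation CSV files follow the
clinician habit of an inclusive last frame; `read_annotations` converts
(`end_frame_exclusive = last_frame_inclusive + 1`).  Whether a clinical
"end point" frame is inclusive is a file-format convention, not a property
of the method; keeping the conversion in one documented place makes it
auditable.

## Three-class window augmentation

Each event yields `3 × n_shifts` windows (default `n_shifts = 9`, hence 27):
shifted *before* windows `[t_s − L − i, t_s − i)`, shifted *after* windows
`[t_e + i, t_e + L + i)`, and *during* windows centered on the event, base
start `⌊(t_s + t_e − L)/2⌋` shifted by `i = −4..4`.  Flooring the fractional
base (when `t_s + t_e − L` is odd) is deterministic and biases the center by
at most half a frame.

Boundary handling is not dictated by the construction itself, so both
policies are provided.  The default, `pad`, realizes out-of-range windows by
edge-frame replication and preserves the exact 27-count and class balance;
`drop` removes them and logs the imbalance.  Events longer than `L` are
accepted with a warning (the *during* windows then cover only the central
`L` frames); with `L = 20` and clinical durations ≤ 13 frames this does not
arise at the published operating point.

## Classifier

The detection pipeline only requires a `predict_proba(window) -> (p0, p1,
p2)` backend, so any spatiotemporal network can be plugged in.  The bundled
reference backend is deliberately desk-scale:

* spatial average-pooling stem down to ~16×16 (`stem_pool`, auto-chosen as
  `min(H, W) // 16`) — scene features several pixels wide at 64×64 survive
  this and it is what makes CPU training practical;
* three 3-D convolution blocks (3×3×3 kernels, channels 8/16/32, ReLU,
  average pooling; the first pool is spatial-only so early temporal
  resolution is kept);
* an optional inception-style block: four parallel branches with exactly two
  distinct filter sizes (1×1×1 and 3×3×3), outputs concatenated on channels;
* global average pooling and a linear 3-way softmax head.

Training uses cross-entropy and Adam (lr 1e-3, batch 16, 12 epochs by
default).  All randomness — initialization and per-epoch shuffling — flows
from a single `numpy.random.Generator` seed, so runs are bit-reproducible.
Because logits feed `argmax`, ties resolve toward the lowest class index
(numpy convention), which is stated as the contract.  The layers are written
directly on NumPy (kernel-offset loops rather than im2col) to keep memory
flat; a numerical-gradient test pins the backprop.

Hyperparameters the published configuration does not determine (optimizer,
loss, schedule, epochs) are package defaults chosen for determinism and
CPU feasibility; the reference network makes no claim of matching a
large-scale pre-trained video network.  Pre-trained weights are explicitly
out of scope.

## Boundary decoding

Per-window classifications must become an interval; the training semantics
pin the boundaries: *before* windows end at `t_s`, *after* windows start at
`t_e`.  The decoder therefore:

1. takes `argmax` labels at every stride-1 window start;
2. majority-smooths them (width 3 by default; width 1 disables) to suppress
   isolated flips, ties keeping the center label;
3. for each maximal run of *during* labels sets `t̂_s = (start of the
   adjacent preceding class-0 window) + L` and `t̂_e = start of the adjacent
   following class-2 window`;
4. falls back to `run-window center ∓ half the typical event duration`
   (default 4 frames ≈ 0.292 s × 15 fps) when the needed transition is
   absent, and rebuilds both boundaries from the run center if the
   transition-derived interval is inverted;
5. reports the mean class-1 probability over the run as the detection
   confidence.

With labels assigned analytically by the three class rules (class 0 if the
window precedes the event entirely, class 2 if it follows it, class 1 if it
overlaps), this decoder recovers `t_s` and `t_e` *exactly* whenever the
event has at least one window of context on each side — a property the test
suite checks on random events.  Multiple detections per clip are allowed
(maximal runs are decoded independently), and stride defaults to 1 because
events can be a single frame long.

## Evaluation

Temporal IOU counts frames: `|a ∩ b| / |a ∪ b|`.  A detection is a true
positive when its IOU with a ground-truth event **strictly** exceeds the
threshold; matching is greedy one-to-one in descending IOU order per clip
(deterministic, and standard in detection evaluation).  Precision, recall,
F1, miss rate `FN/(TP+FN)`, mean ± SD IOU, and mean ± SD absolute start/end
errors in seconds follow.  With one-to-one matching, `F1 = 2·TP /
(#detections + #events)`, so F1 is non-increasing in the IOU threshold —
the FROC curve (default grid 0.05..0.95, 19 points) is monotone by
construction.  Reports always carry the threshold they were computed at;
the default 0.1 is deliberately permissive and flagged as arbitrary.

Cross-validation folds are grouped by participant: a seeded shuffle breaks
ties, participants are sorted by descending event count and assigned
greedily to the least-loaded fold whose size cap (⌈n/k⌉, with exactly
`n mod k` folds allowed the extra member) is not exhausted.  With 27
participants and `k = 5` this yields test folds of 5–6 participants,
pairwise disjoint and jointly exhaustive.

## Synthetic scenes

The generator emulates the geometry of a lateral fluoroscopic view, not its
radiography: a bright soft-edged disk (bolus) descends a vertical column,
and a smaller marker (hyoid stand-in) sits low in the frame.  The reflex
begins exactly when the bolus head reaches a fixed trigger height (the
mandibular-ramus semantics of the clinical ground-truth definition): before
`t_s` the bolus drifts at `pre_speed` (0.25 px/frame at 64×64), during
`[t_s, t_e)` it translates at `reflex_speed` (2.2 px/frame) while the marker
elevates by 10 px, and afterwards it drifts on below the trigger.
Anchoring the trajectory to the trigger is what makes bolus height a
*consistent* cue rather than a spurious one correlated with event time.
Gaussian pixel noise (σ = 0.02) and a participant-specific background
offset are added; grayscale frames are replicated to 3 channels.

Event durations are drawn from a discrete distribution on 1..13 frames that
rises linearly to a peak at 4 and decays geometrically (ratio 0.62) above
it; its mean is 4.374 frames = 0.2916 s, matching the clinical duration
statistics the generator emulates (a symmetric triangular shape on the same
support would have meant 0.40 s, which those statistics rule out).
Annotations are exact by construction, and a frame-difference energy
statistic is strictly higher inside annotated frames for σ ≲ 0.05, which is
the generator's learnability guarantee.

What the scenes do **not** model: anatomical appearance and contrast,
bolus-consistency effects, aspiration or penetration, camera shake,
annotation disagreement.  Passing end-to-end tests on them demonstrates the
framework's correctness and trainability, not clinical accuracy.

## Problem sizes and defaults

The package's standard experiment — used by the end-to-end test and by
`scripts/acceptance.py` — is 50 clips (≈ 60–72 frames each, 64×64) from 10
synthetic participants, 40 clips (1,080 windows) for training and the 10
clips of two held-out participants for testing, `L = 20`, stride 1, IOU
threshold 0.1.  This trains in ≈ 3 minutes on one CPU and, across development
seeds, finds the reflex in 90–100 % of held-out clips with mean boundary
errors of 0.04–0.15 s.  Full 224×224 geometry is available via
`SceneConfig(frame_size=(224, 224))` and scales the scene accordingly.

## Known limitations

* The reference classifier exhibits a small late bias (≈ 1–2 frames) at both
  boundaries: windows in which the event barely protrudes are visually close
  to *before* windows, and the augmentation provides no supervision between
  "ends at `t_s`" and "centered".  Single-frame events are therefore the
  hardest to localize, exactly as in the clinical setting.
* The decoder reading of "how per-window labels become an interval" is one
  defensible completion of the training semantics; alternatives (run-extent
  or probability-weighted boundaries) would slot in behind the same API.
* Window-level accuracy and event-level recall are related but distinct
  success measures; both are reported, labeled distinctly, and should not be
  conflated.
* FPS resampling is integer-stride only (30 → 15 drops every other frame);
  non-integer ratios raise rather than interpolate frames that were never
  recorded.
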