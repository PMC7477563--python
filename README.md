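# reflexloc

Temporal localization of the **pharyngeal swallowing reflex** in
videofluoroscopic swallowing study (VFSS) clips.

The pharyngeal swallowing reflex is the brief involuntary event that moves
the bolus through the pharynx while protecting the airway.  Its response time
is a key clinical indicator for dysphagia assessment, yet it lasts only
0.067–0.867 s (1–13 frames at 15 fps) — far shorter than the fixed-length
clip a spatiotemporal video classifier consumes, and hard to time reliably by
eye.  `reflexloc` is a complete, CPU-friendly implementation of a detection
framework for such very short events, aimed at researchers in medical video
analysis who want to study or extend the method without access to clinical
recordings.

## The method

Let an annotated reflex occupy frames `[t_s, t_e)` of a clip and let `L` be
the classifier's window length (default `L = 20` frames at 15 fps).  Instead
of classifying the tiny event directly, each event is expanded into **27
fixed-length windows in three classes**:

* class 0 (*before*): `[t_s − L − i, t_s − i)` for `i = 0..8` — the `i = 0`
  window ends right at the reflex onset;
* class 1 (*during*): `[(t_s + t_e − L)/2 + i, (t_s + t_e + L)/2 + i)` for
  `i = −4..4` — windows centered on the event;
* class 2 (*after*): `[t_e + i, t_e + L + i)` for `i = 0..8` — the `i = 0`
  window starts right at the reflex offset.

A three-class 3-D convolutional network is trained on these windows, slid
across a test clip at stride 1, and the resulting label sequence is decoded
into a predicted interval: the last *before* window pins `t̂_s`, the first
*after* window pins `t̂_e`, with a run-center fallback.  Predictions are
matched to ground truth by **temporal intersection-over-union**
(`IOU = |∩| / |∪|` in frames); matched pairs give precision, recall, F1,
boundary time errors in seconds, and an FROC curve of F1 versus IOU
threshold.  Cross-validation is grouped by participant so no subject appears
in both train and test folds.

The classifier backend is pluggable (anything with
`predict_proba(window) -> 3-vector`); the bundled reference backend is a
small NumPy 3-D conv net with an optional inception-style block (four
parallel convolutions, 1×1×1 and 3×3×3 filters, channel-concatenated) that
trains on one CPU in minutes.  A synthetic fluoroscopy generator renders
clips in which a bolus disk descends to a trigger landmark, translates
rapidly during exactly the annotated frames, and a hyoid-like marker elevates
— so the full chain is trainable and testable without patient data.

## Worked example

```python
import numpy as np
from reflexloc import EventAnnotation, augment_event, temporal_iou
from reflexloc.detection import classify_window_by_rule, decode_interval

ann = EventAnnotation("clip0", "p0", start_frame=30,
                      end_frame_exclusive=36, fps=15.0)
windows = augment_event(ann, L=20, clip_n_frames=64, boundary_policy="pad")
print("windows:", len(windows))
for label in (0, 1, 2):
    sel = [w for w in windows if w.label == label]
    print(f"class {label}: {len(sel)} windows, first span "
          f"[{sel[0].start}, {sel[0].end})")

scored = [(s, np.eye(3)[classify_window_by_rule(s, 20, 30, 36)])
          for s in range(0, 45)]
det = decode_interval(scored, L=20, clip_id="clip0")[0]
print(f"decoded interval: [{det.start_frame}, {det.end_frame_exclusive}), "
      f"confidence {det.confidence:.2f}")
print(f"temporal IOU vs truth: {temporal_iou(det.interval, (30, 36)):.3f}")
```

prints

```
windows: 27
class 0: 9 windows, first span [10, 30)
class 1: 9 windows, first span [19, 39)
class 2: 9 windows, first span [36, 56)
decoded interval: [30, 36), confidence 1.00
temporal IOU vs truth: 1.000
```

The 27 windows are the per-event training set (9 per class); with
analytically assigned labels the decoder recovers the annotated interval
`[30, 36)` exactly, so any residual boundary error in practice comes from
the classifier, not the decoder.

## Command line

```bash
reflexloc simulate --out data/ --n-clips 20 --participants 10 --seed 0
reflexloc augment  --annotations data/annotations.csv --out manifest.csv
reflexloc train    --clips data/ --annotations data/annotations.csv \
                   --seed 0 --out model.npz
reflexloc detect   --model model.npz --clips data/ --out detections.csv
reflexloc evaluate --detections detections.csv \
                   --annotations data/annotations.csv --out report.json
reflexloc crossval --n-clips 20 --participants 10 --k 5 --seed 0 --out cv.json
```

## Layout

| module | role |
| --- | --- |
| `reflexloc.data_io` | clips, annotations, normalization, CSV dialect |
| `reflexloc.augmentation` | 27-window three-class expansion of an event |
| `reflexloc.classifier` | backend contract, reference 3-D conv net, inception block |
| `reflexloc.nn` | NumPy layers with backprop used by the reference net |
| `reflexloc.detection` | sliding scan and boundary decoding |
| `reflexloc.evaluation` | IOU matching, reports, FROC, grouped k-fold |
| `reflexloc.synthetic` | fluoroscopy-like scene generator |
| `reflexloc.pipeline` / `reflexloc.cli` | orchestration and console entry point |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
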