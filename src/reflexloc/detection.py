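"""Sliding-window scan and boundary decoding.

The classifier labels every length-L window of a clip as before (0), during
(1) or after (2) the reflex.  Decoding turns that label sequence into a
predicted interval.  The training semantics pin the boundaries: a class-0
window *ends* at the reflex onset ``t_s`` and a class-2 window *starts* at
the offset ``t_e``.  So for each maximal run of class-1 labels:

* predicted start = (start of the last class-0 window immediately preceding
  the run) + L, falling back to (first run window's center minus half the
  typical event duration) when no class-0 window precedes;
* predicted end = start of the first class-2 window immediately following the
  run, with the symmetric fallback.

If the transition-derived interval is inverted (possible on degenerate label
sequences), both boundaries are rebuilt from the run center.  Labels are
majority-smoothed first to suppress isolated flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import WindowClassifier
from .data_io import FrameClip

__all__ = [
    "Detection",
    "slide_and_classify",
    "decode_interval",
    "detect",
    "classify_window_by_rule",
    "smooth_labels",
]

logger = logging.getLogger(__name__)

#: Typical reflex duration in frames (mean 0.292 s at 15 fps), used by the
#: center fallback when no boundary transition is available.
DEFAULT_EVENT_FRAMES = 4


@dataclass(frozen=True)
class Detection:
    """A predicted reflex interval ``[start_frame, end_frame_exclusive)``.

    ``confidence`` is the mean class-1 probability over the supporting run of
    windows; ``label_sequence`` keeps the smoothed per-window labels for
    diagnostics.
    """

    clip_id: str
    start_frame: int
    end_frame_exclusive: int
    confidence: float
    label_sequence: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame_exclusive:
            raise ValueError(
                f"invalid interval [{self.start_frame}, "
                f"{self.end_frame_exclusive})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1]: {self.confidence}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start_frame, self.end_frame_exclusive


def slide_and_classify(
    model: WindowClassifier,
    clip: FrameClip,
    L: int,
    stride: int = 1,
) -> list[tuple[int, np.ndarray]]:
    """Classify every length-L window at starts ``0, stride, 2*stride, ...``.

    Returns ``(start, probability 3-vector)`` pairs in temporal order.  Raises
    if the clip is shorter than one window.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if clip.n_frames < L:
        raise ValueError(
            f"{clip.clip_id}: clip has {clip.n_frames} frames, shorter than "
            f"the window length L={L}"
        )
    starts = list(range(0, clip.n_frames - L + 1, stride))
    batch_fn = getattr(model, "predict_proba_batch", None)
    if batch_fn is not None:
        windows = np.stack([clip.frames[s:s + L] for s in starts])
        probs = batch_fn(windows)
        return [(s, probs[i]) for i, s in enumerate(starts)]
    return [(s, np.asarray(model.predict_proba(clip.frames[s:s + L]),
                           dtype=np.float64)) for s in starts]


def smooth_labels(labels: np.ndarray, width: int) -> np.ndarray:
    """Sliding-majority filter; ties keep the center label; width 1 = no-op."""
    if width % 2 != 1 or width < 1:
        raise ValueError(f"smoothing width must be a positive odd integer: {width}")
    if width == 1 or len(labels) == 0:
        return labels.copy()
    half = width // 2
    out = labels.copy()
    n = len(labels)
    for i in range(n):
        seg = labels[max(0, i - half): min(n, i + half + 1)]
        counts = np.bincount(seg, minlength=3)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if len(winners) == 1:
            out[i] = winners[0]
    return out


def _runs(labels: np.ndarray, value: int) -> list[tuple[int, int]]:
    """Maximal runs of ``value`` as (first index, last index) pairs."""
    runs, start = [], None
    for i, lab in enumerate(labels):
        if lab == value and start is None:
            start = i
        elif lab != value and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(labels) - 1))
    return runs


def decode_interval(
    scored: list[tuple[int, np.ndarray]],
    L: int,
    smoothing_width: int = 3,
    typical_event_frames: int = DEFAULT_EVENT_FRAMES,
    clip_id: str = "",
    clip_n_frames: int | None = None,
) -> list[Detection]:
    """Decode the scored window sequence into predicted reflex intervals.

    One Detection per maximal run of class-1 labels, ordered by descending
    confidence.  An empty list (no class-1 run) is a miss, not an error.
    """
    if not scored:
        return []
    starts = np.asarray([s for s, _ in scored])
    probs = np.stack([p for _, p in scored])
    labels = smooth_labels(probs.argmax(axis=1), smoothing_width)

    detections: list[Detection] = []
    for a, b in _runs(labels, 1):
        half_d = typical_event_frames / 2.0
        # onset from the last preceding class-0 window, if it is adjacent
        if a > 0 and labels[a - 1] == 0:
            t_hat_s = int(starts[a - 1] + L)
        else:
            t_hat_s = int(round(starts[a] + L / 2.0 - half_d))
        # offset from the first following class-2 window, if adjacent
        if b + 1 < len(labels) and labels[b + 1] == 2:
            t_hat_e = int(starts[b + 1])
        else:
            t_hat_e = int(round(starts[b] + L / 2.0 + half_d))
        if t_hat_e <= t_hat_s:
            # degenerate transitions: rebuild both boundaries around the
            # run's center
            center = (starts[a] + starts[b]) / 2.0 + L / 2.0
            t_hat_s = int(round(center - half_d))
            t_hat_e = max(t_hat_s + 1, int(round(center + half_d)))
        if clip_n_frames is not None:
            t_hat_s = max(0, min(t_hat_s, clip_n_frames - 1))
            t_hat_e = max(t_hat_s + 1, min(t_hat_e, clip_n_frames))
        else:
            t_hat_s = max(0, t_hat_s)
            t_hat_e = max(t_hat_s + 1, t_hat_e)
        confidence = float(np.clip(probs[a:b + 1, 1].mean(), 0.0, 1.0))
        detections.append(
            Detection(
                clip_id=clip_id,
                start_frame=t_hat_s,
                end_frame_exclusive=t_hat_e,
                confidence=confidence,
                label_sequence=tuple(int(v) for v in labels),
            )
        )
    detections.sort(key=lambda d: -d.confidence)
    return detections


def detect(
    model: WindowClassifier,
    clip: FrameClip,
    L: int,
    stride: int = 1,
    smoothing_width: int = 3,
    typical_event_frames: int = DEFAULT_EVENT_FRAMES,
) -> list[Detection]:
    """Scan a clip and decode predicted reflex intervals.

    Composition of :func:`slide_and_classify` and :func:`decode_interval`;
    any decoded interval violating ``start < end`` is discarded and logged
    (the Detection constructor enforces the invariant).
    """
    scored = slide_and_classify(model, clip, L, stride)
    try:
        return decode_interval(
            scored, L, smoothing_width, typical_event_frames,
            clip_id=clip.clip_id, clip_n_frames=clip.n_frames,
        )
    except ValueError as exc:  # pragma: no cover - guarded upstream
        logger.warning("%s: discarded invalid detection: %s", clip.clip_id, exc)
        return []


def classify_window_by_rule(start: int, L: int, t_s: int, t_e: int) -> int:
    """Analytic window label from the three class definitions (no learning).

    A window entirely before the event ``[t_s, t_e)`` is class 0, entirely
    after is class 2, and any window overlapping the event is class 1.  Used
    as the oracle labeler when validating the decoder.
    """
    if start + L <= t_s:
        return 0
    if start >= t_e:
        return 2
    return 1
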