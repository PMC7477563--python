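"""Three-class interval augmentation for very short events.

A swallowing reflex lasts 1-13 frames at 15 fps -- far shorter than the
fixed-length window a spatiotemporal classifier consumes.  Instead of
classifying the event directly, each annotated event ``[t_s, t_e)`` yields 27
fixed-length windows in three classes:

* class 0 (*before*): 9 windows ``[t_s - L - i, t_s - i)`` for ``i = 0..8``;
  the ``i = 0`` window ends right at the reflex onset.
* class 1 (*during*): 9 windows centered on the event; the base window starts
  at ``floor((t_s + t_e - L) / 2)`` and is shifted by ``i = -4..+4``.
* class 2 (*after*): 9 windows ``[t_e + i, t_e + L + i)`` for ``i = 0..8``;
  the ``i = 0`` window starts right at the reflex offset.

Windows near clip edges are either realized by edge-frame replication
(``pad``, the default, which preserves the 27-sample count and class balance)
or removed (``drop``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import EventAnnotation, FrameClip

__all__ = [
    "WindowSample",
    "windows_before",
    "windows_during",
    "windows_after",
    "augment_event",
    "extract_window",
]

logger = logging.getLogger(__name__)

LABEL_BEFORE, LABEL_DURING, LABEL_AFTER = 0, 1, 2


@dataclass(frozen=True)
class WindowSample:
    """A fixed-length window ``[start, start + length)`` with a class label.

    ``padded`` is true when part of the window lies outside the clip and must
    be realized by edge-frame replication.
    """

    clip_id: str
    start: int
    length: int
    label: int
    padded: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"window length must be >= 1, got {self.length}")
        if self.label not in (LABEL_BEFORE, LABEL_DURING, LABEL_AFTER):
            raise ValueError(f"label must be in {{0, 1, 2}}, got {self.label}")

    @property
    def end(self) -> int:
        return self.start + self.length


def _check_L(L: int) -> None:
    if L < 1:
        raise ValueError(f"window length L must be a positive integer, got {L}")


def windows_before(
    annotation: EventAnnotation, L: int, n_shifts: int = 9
) -> list[WindowSample]:
    """Class-0 windows ending at most ``n_shifts - 1`` frames before onset."""
    _check_L(L)
    t_s = annotation.start_frame
    return [
        WindowSample(annotation.clip_id, t_s - L - i, L, LABEL_BEFORE)
        for i in range(n_shifts)
    ]


def windows_after(
    annotation: EventAnnotation, L: int, n_shifts: int = 9
) -> list[WindowSample]:
    """Class-2 windows starting at most ``n_shifts - 1`` frames after offset."""
    _check_L(L)
    t_e = annotation.end_frame_exclusive
    return [
        WindowSample(annotation.clip_id, t_e + i, L, LABEL_AFTER)
        for i in range(n_shifts)
    ]


def windows_during(
    annotation: EventAnnotation, L: int, n_shifts: int = 9
) -> list[WindowSample]:
    """Class-1 windows centered on the event center.

    The base start is ``floor((t_s + t_e - L) / 2)`` -- the length-L window
    whose center is closest to the event center -- shifted by
    ``i = -floor(n_shifts/2) .. +floor(n_shifts/2)``.  When ``t_s + t_e - L``
    is odd, flooring biases the center by at most half a frame.
    """
    _check_L(L)
    t_s, t_e = annotation.start_frame, annotation.end_frame_exclusive
    if t_e - t_s > L:
        warnings.warn(
            f"{annotation.clip_id}: event duration {t_e - t_s} exceeds window "
            f"length L={L}; class-1 windows cover only the central L frames",
            stacklevel=2,
        )
    base = (t_s + t_e - L) // 2
    half = n_shifts // 2
    return [
        WindowSample(annotation.clip_id, base + i, L, LABEL_DURING)
        for i in range(-half, n_shifts - half)
    ]


def augment_event(
    annotation: EventAnnotation,
    L: int,
    clip_n_frames: int,
    boundary_policy: str = "pad",
    n_shifts: int = 9,
) -> list[WindowSample]:
    """All three-class windows for one event: ``3 * n_shifts`` samples.

    With the default ``n_shifts=9`` this is the 27-samples-per-event
    construction (9 per class).  ``boundary_policy``:

    * ``"pad"`` -- windows reaching outside ``[0, clip_n_frames)`` are kept and
      flagged ``padded=True``; :func:`extract_window` realizes them by edge
      replication, so the count and class balance are exact.
    * ``"drop"`` -- out-of-range windows are removed (the resulting class
      imbalance is logged).
    """
    if boundary_policy not in ("pad", "drop"):
        raise ValueError(f"boundary_policy must be 'pad' or 'drop', got "
                         f"{boundary_policy!r}")
    samples = (
        windows_before(annotation, L, n_shifts)
        + windows_during(annotation, L, n_shifts)
        + windows_after(annotation, L, n_shifts)
    )
    out: list[WindowSample] = []
    n_dropped = 0
    for s in samples:
        in_range = s.start >= 0 and s.end <= clip_n_frames
        if in_range:
            out.append(s)
        elif boundary_policy == "pad":
            out.append(WindowSample(s.clip_id, s.start, s.length, s.label,
                                    padded=True))
        else:
            n_dropped += 1
    if n_dropped:
        counts = np.bincount([s.label for s in out], minlength=3)
        logger.warning(
            "%s: dropped %d out-of-range windows; per-class counts now %s",
            annotation.clip_id, n_dropped, counts.tolist(),
        )
    return out


def extract_window(clip: FrameClip, sample: WindowSample) -> np.ndarray:
    """Materialize a window as exactly ``sample.length`` frames.

    Out-of-range indices of padded samples are clamped to the nearest valid
    frame (edge replication).  Non-padded samples must lie inside the clip.
    """
    n = clip.n_frames
    idx = np.arange(sample.start, sample.end)
    if not sample.padded:
        if sample.start < 0 or sample.end > n:
            raise ValueError(
                f"{sample.clip_id}: window [{sample.start}, {sample.end}) is "
                f"outside the {n}-frame clip and the sample is not padded"
            )
    idx = np.clip(idx, 0, n - 1)
    return clip.frames[idx]
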