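"""Detection scoring: temporal IOU, matching, report metrics, FROC, grouped CV.

A predicted interval matches a ground-truth interval when their temporal
intersection-over-union (frames of overlap divided by frames of union)
strictly exceeds a threshold.  Matching is greedy one-to-one in descending
IOU order, per clip.  Matched pairs are true positives; unmatched detections
are false positives and unmatched ground truths false negatives.  From the
counts: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
miss rate = FN/(TP+FN).  Boundary time errors are the absolute start/end
frame differences of each matched pair, converted to seconds.

The free-response operating characteristic (FROC) traces the F1 score over an
ascending grid of IOU thresholds.  Cross-validation folds are grouped by
participant so no subject appears on both sides of a split.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import EventAnnotation
from .detection import Detection

__all__ = [
    "MatchResult",
    "EvalReport",
    "temporal_iou",
    "match_detections",
    "compute_report",
    "froc_curve",
    "grouped_kfold",
    "DEFAULT_FROC_GRID",
    "DEFAULT_IOU_THRESHOLD",
]

#: 19-point IOU-threshold grid 0.05 .. 0.95.
DEFAULT_FROC_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 20)
)

#: Threshold used by reports when the caller states none.  Deliberately
#: permissive; every report prints the threshold it was computed at.
DEFAULT_IOU_THRESHOLD = 0.1


def temporal_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Frame-count intersection over union of two half-open intervals."""
    a0, a1 = a
    b0, b1 = b
    if a1 <= a0 or b1 <= b0:
        raise ValueError(f"intervals must be non-empty: {a}, {b}")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union


@dataclass
class MatchResult:
    """Outcome of matching detections to ground truth at one IOU threshold."""

    pairs: list[tuple[Detection, EventAnnotation, float]]
    tp: int
    fp: int
    fn: int
    iou_threshold: float

    def __post_init__(self) -> None:
        assert self.tp == len(self.pairs)


def match_detections(
    detections: Sequence[Detection],
    annotations: Sequence[EventAnnotation],
    iou_threshold: float,
) -> MatchResult:
    """Greedy one-to-one matching per clip, descending IOU, strict threshold."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1]: {iou_threshold}")
    dets_by_clip: dict[str, list[tuple[int, Detection]]] = defaultdict(list)
    for i, d in enumerate(detections):
        dets_by_clip[d.clip_id].append((i, d))
    anns_by_clip: dict[str, list[tuple[int, EventAnnotation]]] = defaultdict(list)
    for j, a in enumerate(annotations):
        anns_by_clip[a.clip_id].append((j, a))

    pairs: list[tuple[Detection, EventAnnotation, float]] = []
    for clip_id, dets in dets_by_clip.items():
        anns = anns_by_clip.get(clip_id, [])
        candidates = []
        for i, d in dets:
            for j, a in anns:
                iou = temporal_iou(d.interval,
                                   (a.start_frame, a.end_frame_exclusive))
                if iou > iou_threshold:
                    candidates.append((iou, i, j, d, a))
        # descending IOU; deterministic tie-break on original indices
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        used_d: set[int] = set()
        used_a: set[int] = set()
        for iou, i, j, d, a in candidates:
            if i in used_d or j in used_a:
                continue
            used_d.add(i)
            used_a.add(j)
            pairs.append((d, a, iou))
    tp = len(pairs)
    return MatchResult(
        pairs=pairs,
        tp=tp,
        fp=len(detections) - tp,
        fn=len(annotations) - tp,
        iou_threshold=iou_threshold,
    )


@dataclass
class EvalReport:
    """Summary metrics for one matching outcome.

    Time errors are in seconds; error and IOU statistics are NaN (and
    ``n_pairs`` is 0) when there are no true positives.
    """

    precision: float
    recall: float
    f1: float
    mean_iou: float
    sd_iou: float
    miss_rate: float
    start_error_mean_s: float
    start_error_sd_s: float
    end_error_mean_s: float
    end_error_sd_s: float
    iou_threshold: float
    tp: int
    fp: int
    fn: int
    n_pairs: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    return float(values.mean()), float(values.std(ddof=0))


def compute_report(match: MatchResult, fps: float) -> EvalReport:
    """Precision/recall/F1, IOU statistics, miss rate and time errors."""
    if fps <= 0:
        raise ValueError(f"fps must be positive: {fps}")
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    miss_rate = fn / (tp + fn) if tp + fn else 0.0

    ious = np.asarray([iou for _, _, iou in match.pairs])
    start_err = np.asarray(
        [abs(d.start_frame - a.start_frame) / fps for d, a, _ in match.pairs]
    )
    end_err = np.asarray(
        [abs(d.end_frame_exclusive - a.end_frame_exclusive) / fps
         for d, a, _ in match.pairs]
    )
    mean_iou, sd_iou = _mean_sd(ious)
    se_m, se_s = _mean_sd(start_err)
    ee_m, ee_s = _mean_sd(end_err)
    return EvalReport(
        precision=precision, recall=recall, f1=f1,
        mean_iou=mean_iou, sd_iou=sd_iou, miss_rate=miss_rate,
        start_error_mean_s=se_m, start_error_sd_s=se_s,
        end_error_mean_s=ee_m, end_error_sd_s=ee_s,
        iou_threshold=match.iou_threshold,
        tp=tp, fp=fp, fn=fn, n_pairs=len(match.pairs),
    )


def froc_curve(
    detections: Sequence[Detection],
    annotations: Sequence[EventAnnotation],
    thresholds: Sequence[float] = DEFAULT_FROC_GRID,
) -> list[tuple[float, float]]:
    """F1 score at each IOU threshold (independent matchings), ascending grid."""
    thresholds = list(thresholds)
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    out = []
    for t in thresholds:
        match = match_detections(detections, annotations, t)
        tp, fp, fn = match.tp, match.fp, match.fn
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        out.append((t, f1))
    return out


def grouped_kfold(
    annotations: Sequence[EventAnnotation],
    k: int = 5,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Participant-grouped k-fold split.

    Every participant's events land wholly inside exactly one fold's test
    set.  Fold participant counts differ by at most one (27 participants at
    k=5 gives folds of 5-6), and event counts are balanced greedily: after a
    seeded shuffle, participants are sorted by descending event count and
    each is assigned to the not-yet-full fold with the fewest events.

    Returns ``k`` pairs ``(train_participant_ids, test_participant_ids)``.
    """
    counts: dict[str, int] = defaultdict(int)
    for a in annotations:
        counts[a.participant_id] += 1
    participants = sorted(counts)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(participants):
        raise ValueError(
            f"k={k} exceeds the {len(participants)} distinct participants"
        )
    rng = np.random.default_rng(seed)
    shuffled = [participants[i] for i in rng.permutation(len(participants))]
    shuffled.sort(key=lambda p: -counts[p])  # stable: seeded order breaks ties

    n = len(participants)
    floor = n // k
    n_ceil = n % k  # folds allowed one extra participant
    fold_members: list[list[str]] = [[] for _ in range(k)]
    fold_events = [0] * k
    for p in shuffled:
        at_ceil = sum(len(m) > floor for m in fold_members)
        best = None
        for f in range(k):
            new_size = len(fold_members[f]) + 1
            if new_size > floor + 1:
                continue
            if new_size == floor + 1 and at_ceil >= n_ceil:
                continue
            if best is None or fold_events[f] < fold_events[best]:
                best = f
        assert best is not None
        fold_members[best].append(p)
        fold_events[best] += counts[p]

    all_ids = set(participants)
    folds = []
    for members in fold_members:
        test = sorted(members)
        train = sorted(all_ids - set(members))
        folds.append((train, test))
    return folds
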