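"""Clip and annotation I/O.

All temporal intervals in this package are half-open ``[a, b)`` with 0-based
frame indices.  Annotation CSV files, in contrast, follow the clinician
convention of an *inclusive* last frame; :func:`read_annotations` converts on
the way in and :func:`write_annotations` converts back on the way out, so the
file format never leaks into the pipeline.

Pixel values are normalized to ``[-1, 1]``; grayscale fluoroscopy frames are
replicated to 3 channels so every stage sees an RGB-shaped stack.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "FrameClip",
    "EventAnnotation",
    "load_clip",
    "read_annotations",
    "write_annotations",
    "normalize_frames",
    "ANNOTATION_COLUMNS",
]

#: Exact header of the annotation CSV dialect (inclusive last frame on disk).
ANNOTATION_COLUMNS = (
    "clip_id",
    "participant_id",
    "start_frame",
    "last_frame_inclusive",
    "fps",
)


@dataclass
class FrameClip:
    """An ordered stack of frames with its frame rate and pixel geometry.

    ``frames`` has shape ``(n_frames, height, width, 3)`` with float values in
    ``[-1, 1]``.  This is the unit every pipeline stage consumes.
    """

    clip_id: str
    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (n, h, w, 3); got {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError(f"fps must be positive; got {self.fps}")
        lo, hi = float(self.frames.min(initial=0)), float(self.frames.max(initial=0))
        if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
            raise ValueError(f"pixel values outside [-1, 1]: [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class EventAnnotation:
    """Ground-truth reflex interval ``[start_frame, end_frame_exclusive)``.

    ``participant_id`` identifies the subject for grouped cross-validation so
    no participant contributes clips to both a train and a test fold.
    """

    clip_id: str
    participant_id: str
    start_frame: int
    end_frame_exclusive: int
    fps: float

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise ValueError(
                f"{self.clip_id}: start_frame must be >= 0, got {self.start_frame}"
            )
        if self.end_frame_exclusive <= self.start_frame:
            raise ValueError(
                f"{self.clip_id}: end_frame_exclusive ({self.end_frame_exclusive}) "
                f"must exceed start_frame ({self.start_frame})"
            )
        if self.fps <= 0:
            raise ValueError(f"{self.clip_id}: fps must be positive, got {self.fps}")

    @property
    def duration_frames(self) -> int:
        return self.end_frame_exclusive - self.start_frame

    @property
    def duration_seconds(self) -> float:
        return self.duration_frames / self.fps


def normalize_frames(raw: np.ndarray) -> np.ndarray:
    """Map raw pixel values onto ``[-1, 1]``.

    8-bit sources use the fixed affine map ``x -> 2*(x/255) - 1`` so that 0 and
    255 hit the interval endpoints exactly; float sources are assumed to lie in
    ``[0, 1]`` and are rescaled the same way (values are clipped defensively).
    """
    raw = np.asarray(raw)
    if raw.dtype == np.uint8:
        x = raw.astype(np.float32) / 255.0
    elif raw.dtype == np.uint16:
        x = raw.astype(np.float32) / 65535.0
    else:
        x = raw.astype(np.float32)
    return np.clip(2.0 * x - 1.0, -1.0, 1.0)


def _to_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.repeat(frame[:, :, None], 3, axis=2)
    if frame.ndim == 3 and frame.shape[2] == 1:
        return np.repeat(frame, 3, axis=2)
    if frame.ndim == 3 and frame.shape[2] >= 3:
        return frame[:, :, :3]
    raise ValueError(f"unsupported frame shape {frame.shape}")


def _read_frame_stack(path: Path) -> tuple[np.ndarray, float | None]:
    """Read raw frames from a directory of images or a multimedia container."""
    import imageio.v3 as iio

    if path.is_dir():
        names = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
        )
        if not names:
            raise IOError(f"no image frames found in directory: {path}")
        frames = [np.asarray(iio.imread(p)) for p in names]
        return np.stack(frames), None
    try:
        frames = np.asarray(iio.imread(path, index=None))
        meta = iio.immeta(path)
        src_fps = float(meta.get("fps")) if meta.get("fps") else None
    except Exception as exc:  # pragma: no cover - depends on host codecs
        raise IOError(f"cannot read video source {path}: {exc}") from exc
    if frames.ndim == 3:  # single image or (n, h, w) grayscale stack
        frames = frames[None] if frames.shape[-1] in (1, 3, 4) else frames
    return frames, src_fps


def load_clip(
    path: str | os.PathLike,
    target_fps: float,
    target_size: tuple[int, int],
    *,
    source_fps: float | None = None,
    clip_id: str | None = None,
) -> FrameClip:
    """Load a clip, resample to ``target_fps``, resize, and normalize.

    Temporal resampling only drops frames at an integer stride (e.g. a 30 fps
    source resampled to 15 fps keeps every 2nd frame); no frames are ever
    synthesized by interpolation.  Spatial resizing is bilinear.

    Parameters
    ----------
    path
        A multimedia container readable by imageio, or a directory of image
        frames in lexicographic order.
    target_fps
        Frame rate of the returned clip; the source fps must be an integer
        multiple of it.
    target_size
        ``(height, width)`` of the returned frames.
    source_fps
        Overrides (or supplies, for frame directories) the source frame rate.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"clip path does not exist: {path}")
    raw, meta_fps = _read_frame_stack(path)
    src_fps = source_fps if source_fps is not None else meta_fps
    if src_fps is None:
        src_fps = target_fps  # frame directories carry no rate; assume target

    ratio = src_fps / target_fps
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-6:
        raise ValueError(
            f"unsupported resampling {src_fps} -> {target_fps} fps: the ratio "
            f"{ratio:g} is not a positive integer (no temporal interpolation)"
        )
    raw = raw[::stride]

    h, w = target_size
    out = np.empty((raw.shape[0], h, w, 3), dtype=np.float32)
    for i, frame in enumerate(raw):
        rgb = _to_rgb(np.asarray(frame))
        norm = normalize_frames(rgb)
        if norm.shape[:2] != (h, w):
            norm = _sk_resize(norm, (h, w), order=1, mode="edge",
                              anti_aliasing=False, preserve_range=True)
        out[i] = norm
    return FrameClip(clip_id=clip_id or path.stem, frames=np.clip(out, -1, 1),
                     fps=float(target_fps))


def read_annotations(path: str | os.PathLike) -> list[EventAnnotation]:
    """Read annotations, converting the on-disk inclusive last frame to the
    internal half-open convention (``end_frame_exclusive = last + 1``)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file does not exist: {path}")
    df = pd.read_csv(path, dtype={"clip_id": str, "participant_id": str})
    if tuple(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(ANNOTATION_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    out: list[EventAnnotation] = []
    for idx, row in df.iterrows():
        try:
            start = int(row["start_frame"])
            last = int(row["last_frame_inclusive"])
            if last < start:
                raise ValueError(
                    f"last_frame_inclusive ({last}) < start_frame ({start})"
                )
            out.append(
                EventAnnotation(
                    clip_id=str(row["clip_id"]),
                    participant_id=str(row["participant_id"]),
                    start_frame=start,
                    end_frame_exclusive=last + 1,
                    fps=float(row["fps"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid annotation row {idx}: {exc}") from exc
    return out


def write_annotations(
    annotations: Sequence[EventAnnotation], path: str | os.PathLike
) -> None:
    """Write annotations in the CSV dialect (inclusive last frame on disk).

    Round-trip identity with :func:`read_annotations` holds by construction.
    """
    rows = [
        {
            "clip_id": a.clip_id,
            "participant_id": a.participant_id,
            "start_frame": a.start_frame,
            "last_frame_inclusive": a.end_frame_exclusive - 1,
            "fps": a.fps,
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write annotations to {path}: {exc}") from exc
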