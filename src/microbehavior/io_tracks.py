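"""Readers for landmark-track tables and interval annotations.

A *landmark track* is the per-frame output of a standard face tracker: a CSV
with a timestamp, three head-rotation angles (``pose_Rx``, ``pose_Ry``,
``pose_Rz``, radians) and 68 facial points as ``x_0..x_67`` / ``y_0..y_67``
pixel columns.  An *annotation file* is the CSV export of an interval
annotation tool: one row per labeled behavior bout
(``participant,label,start_sec,end_sec``).

Frame-level label codes use the fixed map other=0, nodding=1, speaking=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_LANDMARKS = 68

#: Closed annotation vocabulary; anything else is a validation error.
LABEL_VOCABULARY = ("nodding", "speaking")

#: Integer frame codes.  "other" (no annotated behavior) keeps the default 0.
LABEL_CODES = {"other": 0, "nodding": 1, "speaking": 2}
CODE_LABELS = {code: label for label, code in LABEL_CODES.items()}

_X_COLUMNS = tuple(f"x_{i}" for i in range(N_LANDMARKS))
_Y_COLUMNS = tuple(f"y_{i}" for i in range(N_LANDMARKS))
_POSE_COLUMNS = ("pose_Rx", "pose_Ry", "pose_Rz")


class TrackFormatError(ValueError):
    """A landmark-track or annotation file violates the expected layout."""


@dataclass
class FaceTrack:
    """One participant's per-frame landmark/rotation time series.

    Attributes
    ----------
    participant_id
        Identifier shared with the matching annotation track.
    frame_rate
        Frames per second (> 0).
    timestamps
        Seconds per frame, shape ``(n_frames,)``, non-decreasing.
    pose_R
        Head rotations in radians, shape ``(n_frames, 3)`` ordered
        (pose_Rx, pose_Ry, pose_Rz).
    landmarks
        Facial points in pixels, shape ``(n_frames, 68, 2)`` with the last
        axis ordered (x, y).
    """

    participant_id: str
    frame_rate: float
    timestamps: np.ndarray
    pose_R: np.ndarray
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pose_R = np.asarray(self.pose_R, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        n = self.timestamps.shape[0]
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if self.pose_R.shape != (n, 3):
            raise ValueError(
                f"pose_R must have shape ({n}, 3), got {self.pose_R.shape}"
            )
        if self.landmarks.shape != (n, N_LANDMARKS, 2):
            raise ValueError(
                f"landmarks must have shape ({n}, {N_LANDMARKS}, 2), "
                f"got {self.landmarks.shape}"
            )
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class AnnotationTrack:
    """Labeled behavior intervals for one participant.

    ``intervals`` is a list of ``(label, start_sec, end_sec)`` tuples with
    ``label`` drawn from :data:`LABEL_VOCABULARY` and ``start < end``.
    """

    participant_id: str
    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, start, end in self.intervals:
            if label not in LABEL_VOCABULARY:
                raise ValueError(
                    f"unknown label {label!r}; expected one of {LABEL_VOCABULARY}"
                )
            if not start < end:
                raise ValueError(
                    f"interval start must precede end, got [{start}, {end}]"
                )


@dataclass
class FrameLabels:
    """One integer behavior code per frame (other=0, nodding=1, speaking=2)."""

    participant_id: str
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if not np.isin(self.codes, list(CODE_LABELS)).all():
            raise ValueError(f"codes must be drawn from {sorted(CODE_LABELS)}")


def _required_track_columns() -> tuple[str, ...]:
    return ("timestamp",) + _POSE_COLUMNS + _X_COLUMNS + _Y_COLUMNS


def _coerce_numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    numeric = df[list(columns)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise TrackFormatError(
            f"{path}: non-numeric value in column '{col}' at data row {row}"
        )
    return numeric


def read_landmark_track(
    path: str | Path,
    participant_id: str,
    frame_rate: float | None = None,
) -> FaceTrack:
    """Read a tracker-style landmark CSV into a :class:`FaceTrack`.

    Parameters
    ----------
    path
        CSV with one header row; required columns ``timestamp``,
        ``pose_Rx/Ry/Rz`` and ``x_0..x_67`` / ``y_0..y_67``.  Header names may
        carry padding whitespace (common in tracker exports); extra columns
        are ignored.
    participant_id
        Identifier to attach to the track.
    frame_rate
        Override for the frame rate.  When ``None`` it is inferred as the
        inverse of the median timestamp spacing.

    Raises
    ------
    TrackFormatError
        If a required column is missing or a cell is non-numeric.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    required = _required_track_columns()
    for col in required:
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")
    numeric = _coerce_numeric(df, required, path)

    timestamps = numeric["timestamp"].to_numpy()
    if frame_rate is None:
        if len(timestamps) < 2:
            raise TrackFormatError(
                f"{path}: cannot infer frame rate from {len(timestamps)} frame(s); "
                "pass frame_rate explicitly"
            )
        spacing = float(np.median(np.diff(timestamps)))
        if spacing <= 0:
            raise TrackFormatError(f"{path}: non-positive median timestamp spacing")
        frame_rate = 1.0 / spacing

    pose = numeric[list(_POSE_COLUMNS)].to_numpy()
    xs = numeric[list(_X_COLUMNS)].to_numpy()
    ys = numeric[list(_Y_COLUMNS)].to_numpy()
    landmarks = np.stack([xs, ys], axis=2)
    return FaceTrack(
        participant_id=participant_id,
        frame_rate=float(frame_rate),
        timestamps=timestamps,
        pose_R=pose,
        landmarks=landmarks,
    )


def read_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read an interval-annotation CSV into one track per participant.

    The file has columns ``participant,label,start_sec,end_sec``.  Intervals
    are kept in file order; participants are returned in order of first
    appearance.  An empty file (header only) yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("participant", "label", "start_sec", "end_sec"):
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")
    tracks: dict[str, AnnotationTrack] = {}
    for row_idx, row in df.iterrows():
        label = str(row["label"]).strip()
        if label not in LABEL_VOCABULARY:
            raise ValueError(
                f"{path}: row {row_idx}: unknown label {label!r}; "
                f"expected one of {LABEL_VOCABULARY}"
            )
        start, end = float(row["start_sec"]), float(row["end_sec"])
        if not start < end:
            raise ValueError(
                f"{path}: row {row_idx}: interval start {start} must precede end {end}"
            )
        pid = str(row["participant"])
        track = tracks.setdefault(pid, AnnotationTrack(pid, []))
        track.intervals.append((label, start, end))
    return list(tracks.values())


def frame_labels(track: FaceTrack, ann: AnnotationTrack) -> FrameLabels:
    """Rasterize interval annotations onto the track's frame grid.

    Frame *i* receives the code of the interval containing ``timestamps[i]``
    under half-open membership ``start <= t < end``; uncovered frames stay 0.
    When nodding and speaking intervals both cover a frame, nodding wins
    (behaviors are treated as mutually exclusive and the rarer class keeps
    its scarce positives).
    """
    if track.participant_id != ann.participant_id:
        raise ValueError(
            f"participant mismatch: track {track.participant_id!r} "
            f"vs annotations {ann.participant_id!r}"
        )
    codes = np.zeros(track.n_frames, dtype=int)
    t = track.timestamps
    # Two passes so nodding overwrites speaking wherever both apply.
    for wanted in ("speaking", "nodding"):
        for label, start, end in ann.intervals:
            if label == wanted:
                codes[(t >= start) & (t < end)] = LABEL_CODES[label]
    return FrameLabels(participant_id=track.participant_id, codes=codes)
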