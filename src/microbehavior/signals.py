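"""Derivation of 1-D behavior signals from a face track.

Two signals carry the behaviors of interest: the head-pitch rotation
(``pose_Rx``) oscillates during nodding, and the aperture between the inner
upper-lip and inner lower-lip midpoints (points 62 and 66 of the standard
68-landmark scheme, 0-based) oscillates during speaking.  Signals are raw —
no smoothing, gap filling, or face-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tracks import FaceTrack

#: Inner-lip midpoint indices (0-based) in the 68-point scheme.
UPPER_LIP_POINT = 62
LOWER_LIP_POINT = 66

LIP_SIGNAL_NAME = f"lip_{UPPER_LIP_POINT}_{LOWER_LIP_POINT}"

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class BehaviorSignal:
    """A named per-frame scalar signal (pixels for distances, radians for rotations)."""

    name: str
    values: np.ndarray
    participant_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")

    def __len__(self) -> int:
        return self.values.shape[0]


def lip_distance_signal(track: FaceTrack) -> BehaviorSignal:
    """Per-frame Euclidean distance between landmarks 62 and 66 (lip aperture)."""
    diff = track.landmarks[:, UPPER_LIP_POINT, :] - track.landmarks[:, LOWER_LIP_POINT, :]
    values = np.hypot(diff[:, 0], diff[:, 1])
    return BehaviorSignal(LIP_SIGNAL_NAME, values, track.participant_id)


def rotation_signal(track: FaceTrack, axis: str) -> BehaviorSignal:
    """Copy of one head-rotation channel; ``axis`` is 'x', 'y' or 'z'."""
    if axis not in _AXIS_INDEX:
        raise ValueError(f"unknown rotation axis {axis!r}; expected one of x, y, z")
    values = track.pose_R[:, _AXIS_INDEX[axis]].copy()
    return BehaviorSignal(f"pose_R{axis}", values, track.participant_id)


def derive_signals(track: FaceTrack, names: tuple[str, ...] | list[str]) -> list[BehaviorSignal]:
    """Derive the named signals from a track.

    Recognized names: ``pose_Rx``/``pose_Ry``/``pose_Rz`` and ``lip_62_66``.
    """
    out = []
    for name in names:
        if name == LIP_SIGNAL_NAME:
            out.append(lip_distance_signal(track))
        elif name.startswith("pose_R") and len(name) == 7:
            out.append(rotation_signal(track, name[-1]))
        else:
            raise ValueError(f"unknown signal name {name!r}")
    return out
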