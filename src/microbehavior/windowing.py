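"""Sliding-window segmentation with majority-vote labels.

Windows are fixed-width (default 32 frames, about 1.06 s at 29.97 fps),
advanced by a fixed step (default 16 frames, 50% overlap), aligned to frame 0
and half-open; trailing partial windows are dropped.  Each window's class is
the most frequent per-frame code inside it, with ties broken by the priority
nodding > speaking > other so rare positive classes are favored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tracks import FrameLabels
from .signals import BehaviorSignal

#: Tie-break priority: lower rank wins on equal counts.
_TIE_RANK = {1: 0, 2: 1, 0: 2}


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: ``width`` frames advanced by ``step`` frames."""

    width: int = 32
    step: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.width):
            raise ValueError(
                f"require 0 < step <= width, got step={self.step}, width={self.width}"
            )


@dataclass
class WindowSample:
    """One analysis window: channel slices, majority label, provenance."""

    participant_id: str
    start: int  # frame index, inclusive
    end: int    # frame index, exclusive
    label: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)


def make_windows(n_frames: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open ``(start, end)`` frame spans covering ``n_frames``.

    Returns ``[(k*step, k*step + width)]`` for
    ``k = 0 .. floor((n_frames - width) / step)``; empty when the track is
    shorter than one window.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    if n_frames < spec.width:
        return []
    count = (n_frames - spec.width) // spec.step + 1
    return [(k * spec.step, k * spec.step + spec.width) for k in range(count)]


def majority_label(codes: np.ndarray) -> int:
    """Most frequent code in a window; ties go nodding > speaking > other."""
    codes = np.asarray(codes, dtype=int)
    if codes.size == 0:
        raise ValueError("majority_label requires a non-empty code sequence")
    counts = np.bincount(codes, minlength=3)
    best = counts.max()
    candidates = [c for c in range(counts.size) if counts[c] == best]
    return min(candidates, key=lambda c: _TIE_RANK.get(c, 3 + c))


def window_dataset(
    signals: list[BehaviorSignal],
    labels: FrameLabels,
    spec: WindowSpec,
) -> list[WindowSample]:
    """Cut all signals and labels of one participant into labeled windows."""
    if not signals:
        raise ValueError("at least one signal is required")
    n = len(labels.codes)
    for sig in signals:
        if sig.participant_id != labels.participant_id:
            raise ValueError(
                f"participant mismatch: signal {sig.participant_id!r} "
                f"vs labels {labels.participant_id!r}"
            )
        if len(sig) != n:
            raise ValueError(
                f"signal {sig.name!r} has length {len(sig)}, labels have {n}"
            )
    samples = []
    for start, end in make_windows(n, spec):
        samples.append(
            WindowSample(
                participant_id=labels.participant_id,
                start=start,
                end=end,
                label=majority_label(labels.codes[start:end]),
                channels={s.name: s.values[start:end] for s in signals},
            )
        )
    return samples
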