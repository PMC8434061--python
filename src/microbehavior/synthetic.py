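"""Synthetic meeting sessions: landmark tracks plus ground-truth annotations.

Real meeting recordings of this kind are rarely shareable, so the generator
produces per-participant face-tracker output with the statistical structure
the pipeline assumes:

* a 68-point template face jittered frame by frame;
* non-overlapping behavior events separated by exponential gaps, each
  speaking with probability ``p_speaking``, with gamma-distributed durations
  (shape 4) whose means match observed meeting behavior — 4.01 s for
  speaking bouts, 1.06 s for nods;
* during a nod, the head-pitch channel (pose_Rx) carries a sinusoid at the
  participant's nod rate, shaped by a Hann envelope so the nod starts and
  ends smoothly;
* during speech, the aperture between inner-lip points 62 and 66 follows
  ``baseline + amplitude * |sin(2 pi f_syllable t)|``; the two points are
  placed so the distance is realized exactly;
* per-participant style — nod amplitude and rate drawn once per participant —
  mimics how some people nod shallowly and fast while others nod deeply,
  which is what makes leave-one-participant-out evaluation harder than a
  random split.

Noise is clipped (rotation jitter at 3 sd, lip-distance jitter at 2 sd) so
that excursions beyond those multiples occur only inside true events; this
keeps the generated data's event structure unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tracks import AnnotationTrack, FaceTrack, N_LANDMARKS
from .signals import LOWER_LIP_POINT, UPPER_LIP_POINT

_FLOAT_FORMAT = "%.9f"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one synthetic dataset.

    Durations are in seconds, amplitudes in pixels (lip) or radians (head
    pitch), rates in Hz.  Event durations are gamma-distributed with
    ``duration_shape`` and the class-specific means; gaps between events are
    exponential with mean ``event_gap_mean`` (``inf`` disables events).
    Per-participant nod style is drawn uniformly from the given ranges.
    """

    n_participants: int = 8
    duration: float = 300.0
    frame_rate: float = 29.97
    event_gap_mean: float = 6.0
    p_speaking: float = 0.5
    speaking_duration_mean: float = 4.01
    nodding_duration_mean: float = 1.06
    duration_shape: float = 4.0
    speaking_amplitude: float = 4.0
    syllable_rate: float = 4.0
    nod_amplitude_range: tuple[float, float] = (0.05, 0.30)
    nod_rate_range: tuple[float, float] = (1.0, 3.0)
    landmark_jitter_sd: float = 0.5
    rotation_jitter_sd: float = 0.01
    lip_baseline: float = 6.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.p_speaking <= 1.0):
            raise ValueError("p_speaking must lie in [0, 1]")
        for name in ("duration", "frame_rate", "speaking_duration_mean",
                     "nodding_duration_mean", "duration_shape",
                     "speaking_amplitude", "syllable_rate", "lip_baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.event_gap_mean <= 0:
            raise ValueError("event_gap_mean must be positive (inf allowed)")


def _template_face(center: tuple[float, float] = (320.0, 240.0)) -> np.ndarray:
    """A deterministic, roughly face-shaped 68-point template (pixels)."""
    cx, cy = center
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: lower half-ellipse
    theta = np.linspace(math.pi, 2 * math.pi, 17)
    pts[0:17, 0] = cx + 80 * np.cos(theta)
    pts[0:17, 1] = cy + 100 * np.abs(np.sin(theta))  # chin below center
    # brows 17-26: two arcs
    for i in range(5):
        pts[17 + i] = (cx - 60 + 12 * i, cy - 45 - 4 * math.sin(math.pi * i / 4))
        pts[22 + i] = (cx + 12 + 12 * i, cy - 45 - 4 * math.sin(math.pi * i / 4))
    # nose 27-35
    for i in range(4):
        pts[27 + i] = (cx, cy - 30 + 12 * i)
    for i in range(5):
        pts[31 + i] = (cx - 12 + 6 * i, cy + 22)
    # eyes 36-47: two hexagons
    for eye, ex in ((36, cx - 40), (42, cx + 40)):
        ang = np.linspace(0, 2 * math.pi, 6, endpoint=False)
        pts[eye:eye + 6, 0] = ex + 14 * np.cos(ang)
        pts[eye:eye + 6, 1] = cy - 25 + 7 * np.sin(ang)
    # outer lip 48-59: ellipse
    ang = np.linspace(0, 2 * math.pi, 12, endpoint=False)
    pts[48:60, 0] = cx + 28 * np.cos(ang)
    pts[48:60, 1] = cy + 55 + 12 * np.sin(ang)
    # inner lip 60-67: smaller ellipse; 62/66 are the vertical midpoints
    ang = np.linspace(0, 2 * math.pi, 8, endpoint=False)
    pts[60:68, 0] = cx + 18 * np.cos(ang)
    pts[60:68, 1] = cy + 55 + 6 * np.sin(ang)
    pts[UPPER_LIP_POINT] = (cx, cy + 52)
    pts[LOWER_LIP_POINT] = (cx, cy + 58)
    return pts


def _draw_events(cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[str, float, float]]:
    """Non-overlapping labeled events inside [0, duration]."""
    if not math.isfinite(cfg.event_gap_mean):
        return []
    events = []
    t = rng.exponential(cfg.event_gap_mean)
    while True:
        speaking = rng.random() < cfg.p_speaking
        mean = cfg.speaking_duration_mean if speaking else cfg.nodding_duration_mean
        dur = rng.gamma(cfg.duration_shape, mean / cfg.duration_shape)
        if t + dur > cfg.duration:
            break
        events.append(("speaking" if speaking else "nodding", t, t + dur))
        t = t + dur + rng.exponential(cfg.event_gap_mean)
    return events


def generate_participant(
    cfg: SyntheticConfig,
    participant_id: str,
    seed: int | None = None,
) -> tuple[FaceTrack, AnnotationTrack]:
    """Generate one participant's track and ground-truth annotations.

    ``seed`` defaults to ``cfg.seed``; per-participant style (nod amplitude
    and rate) is drawn from this stream, so different seeds give different
    styles.
    """
    n_frames = int(round(cfg.duration * cfg.frame_rate))
    if n_frames < 32:
        raise ValueError(
            f"duration {cfg.duration}s at {cfg.frame_rate} fps gives only "
            f"{n_frames} frames, shorter than one 32-frame window"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nod_amp = rng.uniform(*cfg.nod_amplitude_range)
    nod_rate = rng.uniform(*cfg.nod_rate_range)
    events = _draw_events(cfg, rng)

    t = np.arange(n_frames) / cfg.frame_rate

    # head rotations: clipped jitter; pitch additionally carries nods
    jit = rng.normal(0.0, cfg.rotation_jitter_sd, size=(n_frames, 3))
    np.clip(jit, -3 * cfg.rotation_jitter_sd, 3 * cfg.rotation_jitter_sd, out=jit)
    pose = jit
    for label, start, end in events:
        if label != "nodding":
            continue
        mask = (t >= start) & (t < end)
        tt = t[mask]
        phase = np.pi * (tt - start) / (end - start)
        envelope = np.sin(phase) ** 2  # Hann: smooth onset/offset
        pose[mask, 0] += nod_amp * np.sin(2 * np.pi * nod_rate * (tt - start)) * envelope

    # lip aperture: baseline + syllable oscillation inside speaking events
    d = np.full(n_frames, cfg.lip_baseline)
    for label, start, end in events:
        if label != "speaking":
            continue
        mask = (t >= start) & (t < end)
        tt = t[mask]
        d[mask] += cfg.speaking_amplitude * np.abs(
            np.sin(2 * np.pi * cfg.syllable_rate * (tt - start))
        )
    d_jit = rng.normal(0.0, cfg.landmark_jitter_sd, size=n_frames)
    np.clip(d_jit, -2 * cfg.landmark_jitter_sd, 2 * cfg.landmark_jitter_sd, out=d_jit)
    d = np.maximum(d + d_jit, 0.0)

    template = _template_face()
    landmarks = template[None, :, :] + rng.normal(
        0.0, cfg.landmark_jitter_sd, size=(n_frames, N_LANDMARKS, 2)
    )
    # place the inner-lip midpoints to realize the aperture exactly
    lip_cx = template[UPPER_LIP_POINT, 0]
    lip_cy = (template[UPPER_LIP_POINT, 1] + template[LOWER_LIP_POINT, 1]) / 2
    landmarks[:, UPPER_LIP_POINT, 0] = lip_cx
    landmarks[:, LOWER_LIP_POINT, 0] = lip_cx
    landmarks[:, UPPER_LIP_POINT, 1] = lip_cy - d / 2
    landmarks[:, LOWER_LIP_POINT, 1] = lip_cy + d / 2

    track = FaceTrack(
        participant_id=participant_id,
        frame_rate=cfg.frame_rate,
        timestamps=t,
        pose_R=pose,
        landmarks=landmarks,
    )
    ann = AnnotationTrack(participant_id=participant_id, intervals=events)
    return track, ann


def generate_dataset(cfg: SyntheticConfig) -> list[tuple[FaceTrack, AnnotationTrack]]:
    """Generate ``cfg.n_participants`` independent participants.

    Per-participant seeds are spawned from the master seed, so each
    participant draws an independent style and event sequence while the whole
    dataset stays reproducible from ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(cfg.n_participants) % (2 ** 31)
    return [
        generate_participant(cfg, f"p{i + 1:02d}", seed=int(seeds[i]))
        for i in range(cfg.n_participants)
    ]


def write_fixture_files(
    pairs: list[tuple[FaceTrack, AnnotationTrack]],
    directory: str | Path,
) -> dict[str, Path]:
    """Write tracker-style landmark CSVs and one pooled annotation CSV.

    Returns a mapping of participant id to its landmark file, plus the key
    ``"annotations"`` for the pooled annotation file.  Files use fixed float
    formatting so identical inputs produce identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ann_rows = []
    for track, ann in pairs:
        data = {"frame": np.arange(track.n_frames), "timestamp": track.timestamps}
        for j, name in enumerate(("pose_Rx", "pose_Ry", "pose_Rz")):
            data[name] = track.pose_R[:, j]
        for i in range(N_LANDMARKS):
            data[f"x_{i}"] = track.landmarks[:, i, 0]
        for i in range(N_LANDMARKS):
            data[f"y_{i}"] = track.landmarks[:, i, 1]
        path = directory / f"{track.participant_id}_landmarks.csv"
        pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        paths[track.participant_id] = path
        for label, start, end in ann.intervals:
            ann_rows.append((ann.participant_id, label, start, end))
    ann_path = directory / "annotations.csv"
    pd.DataFrame(
        ann_rows, columns=["participant", "label", "start_sec", "end_sec"]
    ).to_csv(ann_path, index=False, float_format=_FLOAT_FORMAT)
    paths["annotations"] = ann_path
    return paths
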