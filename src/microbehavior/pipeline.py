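"""End-to-end orchestration: tracks + annotations -> feature table -> scores.

Thin glue over the other modules, shared by the command-line interface and
by scripted use.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import (
    ForestConfig,
    SEED_STAGE_BALANCE,
    balance_downsample,
    derive_seed,
    kfold_eval,
)
from .features import FeatureSpec, extract_features
from .io_tracks import (
    AnnotationTrack,
    FaceTrack,
    frame_labels,
    read_annotations,
    read_landmark_track,
)
from .signals import derive_signals
from .windowing import WindowSpec, window_dataset

TrackPair = tuple[FaceTrack, AnnotationTrack]


def load_fixture_dir(
    directory: str | Path,
    frame_rate: float | None = None,
) -> list[TrackPair]:
    """Load ``<pid>_landmarks.csv`` files and ``annotations.csv`` from a directory.

    Participants without annotation rows get an empty annotation track.
    """
    directory = Path(directory)
    track_paths = sorted(directory.glob("*_landmarks.csv"))
    if not track_paths:
        raise FileNotFoundError(f"no *_landmarks.csv files in {directory}")
    ann_path = directory / "annotations.csv"
    ann_by_pid = {}
    if ann_path.exists():
        ann_by_pid = {a.participant_id: a for a in read_annotations(ann_path)}
    pairs = []
    for path in track_paths:
        pid = path.name[: -len("_landmarks.csv")]
        track = read_landmark_track(path, pid, frame_rate=frame_rate)
        pairs.append((track, ann_by_pid.get(pid, AnnotationTrack(pid, []))))
    return pairs


def feature_table(
    pairs: list[TrackPair],
    window_spec: WindowSpec = WindowSpec(),
    feature_spec: FeatureSpec = FeatureSpec(),
) -> pd.DataFrame:
    """Window every participant and extract the pooled feature table."""
    tables = []
    for track, ann in pairs:
        signals = derive_signals(track, feature_spec.channels)
        labels = frame_labels(track, ann)
        samples = window_dataset(signals, labels, window_spec)
        if samples:
            tables.append(extract_features(samples, feature_spec))
    if not tables:
        raise ValueError("no windows could be formed from the given tracks")
    return pd.concat(tables, ignore_index=True)


def sweep_window_geometry(
    pairs: list[TrackPair],
    widths: tuple[int, ...] = (16, 32, 64),
    overlaps: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75),
    feature_spec: FeatureSpec = FeatureSpec(),
    cfg: ForestConfig = ForestConfig(),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Macro-F1 grid over window width (frames) x overlap (fraction).

    For each combination, windows are re-cut with
    ``step = max(1, round(width * (1 - overlap)))``, the pooled window set is
    re-balanced, and k-fold macro F1 is measured.  Returns a DataFrame with
    widths as rows and overlap fractions as columns.
    """
    grid = {}
    for overlap in overlaps:
        column = []
        for width in widths:
            step = max(1, int(round(width * (1.0 - overlap))))
            table = feature_table(pairs, WindowSpec(width, step), feature_spec)
            balanced = balance_downsample(
                table, derive_seed(seed, SEED_STAGE_BALANCE)
            )
            result = kfold_eval(balanced, k=k, cfg=cfg, seed=seed)
            column.append(result.macro_f1_mean)
        grid[overlap] = column
    return pd.DataFrame(grid, index=list(widths)).rename_axis(
        index="width", columns="overlap"
    )
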