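"""Class balancing, random-forest training, cross-validation and reporting.

The classifier is a random forest (100 trees, Gini impurity, 7 candidate
features per split — the floor of the square root of the 60-feature vector).
Because unannotated frames dominate a meeting, the pooled window set is
balanced once by random downsampling to the minority-class count before
either cross-validation protocol:

* **k-fold** — a plain seeded shuffle into k near-equal folds (not
  stratified, not grouped); stratification is available behind a flag;
* **leave-one-participant-out (LOPO)** — one fold per participant, that
  participant's windows forming the test set, which measures generalization
  to unseen people.

Metrics are per-class precision/recall/F1 aggregated as mean +/- std over
folds, a macro-average F1 over all classes including *other*, and a pooled
confusion matrix in the fixed class order (other, nodding, speaking).

All stochastic steps derive their seeds from one top-level integer via
:func:`derive_seed`, so a run is reproducible from a single value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isqrt

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold

from .features import METADATA_COLUMNS, FeatureSpec, extract_features
from .io_tracks import CODE_LABELS, FaceTrack, FrameLabels
from .signals import derive_signals
from .windowing import WindowSpec, window_dataset

#: Fixed class order for reports and confusion matrices.
CLASS_ORDER = (0, 1, 2)

# Stage offsets for the documented seed-derivation scheme.
SEED_STAGE_BALANCE = 1
SEED_STAGE_SPLIT = 2
SEED_STAGE_FOREST = 3


def derive_seed(seed: int, stage: int) -> int:
    """Stage seed derived from the top-level seed (stable, < 2**31)."""
    return (int(seed) * 7919 + stage) % (2 ** 31)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``max_features=None`` resolves to ``floor(sqrt(n_features))`` at fit time
    (7 for the default 60-feature vector).
    """

    n_trees: int = 100
    criterion: str = "gini"
    max_features: int | None = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1 when set")

    def resolve_max_features(self, n_features: int) -> int:
        if self.max_features is None:
            return isqrt(n_features)
        if self.max_features > n_features:
            raise ValueError(
                f"max_features={self.max_features} exceeds {n_features} features"
            )
        return self.max_features


@dataclass
class EvalResult:
    """Cross-validation outcome: per-class and macro metrics plus confusion.

    ``per_class`` has one row per class (other/nodding/speaking order) with
    mean and std of precision, recall and F1 over folds.  ``confusion`` pools
    all test predictions (rows = true, columns = predicted).
    """

    per_class: pd.DataFrame
    macro_f1_mean: float
    macro_f1_std: float
    confusion: np.ndarray
    classes: tuple[int, ...]
    fold_assignments: np.ndarray = field(repr=False, default=None)

    def metrics_frame(self) -> pd.DataFrame:
        """Report table: one row per class plus a macro-average line."""
        rows = self.per_class.copy()
        macro = pd.DataFrame(
            [{"f1_mean": self.macro_f1_mean, "f1_std": self.macro_f1_std}],
            index=["macro ave."],
        )
        return pd.concat([rows, macro])

    def confusion_frame(self) -> pd.DataFrame:
        names = [CODE_LABELS[c] for c in self.classes]
        return pd.DataFrame(self.confusion, index=names, columns=names)


def split_features(
    table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, participants, feature names)."""
    feature_cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    groups = table["participant"].to_numpy()
    return X, y, groups, feature_cols


def balance_downsample(
    table: pd.DataFrame,
    seed: int,
    label_col: str = "label",
    required_classes: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Downsample every class to the minority-class count (seeded).

    Sampling is uniform without replacement; the result is shuffled
    deterministically.  If ``required_classes`` is given, each must be
    present; otherwise at least two classes are required.
    """
    counts = table[label_col].value_counts().to_dict()
    if required_classes is not None:
        missing = [c for c in required_classes if c not in counts]
        if missing:
            raise ValueError(
                f"class(es) {missing} absent; observed counts: {counts}"
            )
    elif len(counts) < 2:
        raise ValueError(f"need >= 2 classes to balance; observed counts: {counts}")
    rng = np.random.default_rng(seed)
    m = min(counts.values())
    parts = []
    for cls in sorted(counts):
        idx = table.index[table[label_col] == cls].to_numpy()
        parts.append(rng.choice(idx, size=m, replace=False))
    chosen = np.concatenate(parts)
    rng.shuffle(chosen)
    return table.loc[chosen].reset_index(drop=True)


def train_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> RandomForestClassifier:
    """Fit a seeded random forest honoring the configuration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.criterion,
        max_features=cfg.resolve_max_features(X.shape[1]),
        random_state=cfg.seed,
    )
    model.fit(X, y)
    return model


def confusion_metrics(cm: np.ndarray) -> dict[str, np.ndarray | float]:
    """Precision/recall/F1 per class and macro F1 from a confusion matrix.

    Precision is diagonal over column sum, recall diagonal over row sum,
    F1 their harmonic mean; 0/0 is defined as 0.  Macro F1 is the unweighted
    mean over all classes.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_f1": float(f1.mean()),
    }


def _aggregate_folds(
    fold_truths: list[np.ndarray],
    fold_preds: list[np.ndarray],
    classes: tuple[int, ...],
    fold_assignments: np.ndarray,
) -> EvalResult:
    per_fold = {"precision": [], "recall": [], "f1": []}
    macro = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for y_true, y_pred in zip(fold_truths, fold_preds):
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(classes), zero_division=0
        )
        per_fold["precision"].append(p)
        per_fold["recall"].append(r)
        per_fold["f1"].append(f)
        macro.append(f.mean())
        pooled += _sk_confusion(y_true, y_pred, labels=list(classes))
    data = {}
    for metric, values in per_fold.items():
        arr = np.vstack(values)
        data[f"{metric}_mean"] = arr.mean(axis=0)
        data[f"{metric}_std"] = arr.std(axis=0)
    per_class = pd.DataFrame(data, index=[CODE_LABELS[c] for c in classes])
    macro = np.asarray(macro)
    return EvalResult(
        per_class=per_class,
        macro_f1_mean=float(macro.mean()),
        macro_f1_std=float(macro.std()),
        confusion=pooled,
        classes=classes,
        fold_assignments=fold_assignments,
    )


def _present_classes(y: np.ndarray) -> tuple[int, ...]:
    present = set(np.unique(y).tolist())
    return tuple(c for c in CLASS_ORDER if c in present)


def kfold_eval(
    table: pd.DataFrame,
    k: int = 10,
    cfg: ForestConfig = ForestConfig(),
    seed: int = 0,
    stratified: bool = False,
) -> EvalResult:
    """Random-split k-fold cross-validation over a (balanced) feature table."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y, _, _ = split_features(table)
    if X.shape[0] < k:
        raise ValueError(f"dataset of {X.shape[0]} samples cannot form {k} folds")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True,
                            random_state=derive_seed(seed, SEED_STAGE_SPLIT))
    classes = _present_classes(y)
    truths, preds = [], []
    assignments = np.full(X.shape[0], -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        model = train_forest(X[train_idx], y[train_idx], cfg)
        truths.append(y[test_idx])
        preds.append(model.predict(X[test_idx]))
        assignments[test_idx] = fold
    return _aggregate_folds(truths, preds, classes, assignments)


def lopo_eval(
    table: pd.DataFrame,
    cfg: ForestConfig = ForestConfig(),
) -> EvalResult:
    """Leave-one-participant-out cross-validation: one fold per participant."""
    X, y, groups, _ = split_features(table)
    participants = pd.unique(groups)
    if participants.size < 2:
        raise ValueError("leave-one-participant-out needs >= 2 participants")
    classes = _present_classes(y)
    truths, preds = [], []
    assignments = np.full(X.shape[0], -1, dtype=int)
    for fold, pid in enumerate(participants):
        test_mask = groups == pid
        model = train_forest(X[~test_mask], y[~test_mask], cfg)
        truths.append(y[test_mask])
        preds.append(model.predict(X[test_mask]))
        assignments[test_mask] = fold
    return _aggregate_folds(truths, preds, classes, assignments)


def importance_ranking(
    model: RandomForestClassifier,
    feature_names: list[str],
    top_n: int = 5,
    channels: tuple[str, ...] = ("pose_Rx", "lip_62_66"),
) -> pd.DataFrame:
    """Impurity-importance ranking as (rank, function, component, type, weight).

    Feature names follow the ``function_channel_domain`` scheme; ``channels``
    supplies the channel vocabulary needed to split names whose channel part
    itself contains underscores.
    """
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model must be a fitted forest with impurity importances")
    weights = model.feature_importances_
    if len(feature_names) != weights.shape[0]:
        raise ValueError("feature_names length does not match the fitted model")
    rows = []
    for name, weight in zip(feature_names, weights):
        stem, domain = name.rsplit("_", 1)
        component = next(
            (ch for ch in sorted(channels, key=len, reverse=True)
             if stem.endswith("_" + ch)),
            None,
        )
        if component is not None:
            function = stem[: -(len(component) + 1)]
        else:
            function, component = stem.split("_", 1)
        rows.append((function, component, domain, float(weight)))
    table = pd.DataFrame(rows, columns=["function", "component", "type", "weight"])
    table = table.sort_values("weight", ascending=False, kind="mergesort")
    table = table.head(top_n).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def predict_timeline(
    model: RandomForestClassifier,
    track: FaceTrack,
    spec: FeatureSpec,
    window_spec: WindowSpec,
) -> list[dict]:
    """Predict per-window behaviors and merge them into labeled intervals.

    Consecutive windows with the same non-*other* prediction merge into one
    interval spanning the first window's start to the last window's end,
    converted to seconds via the track's frame rate.  Tracks shorter than one
    window yield an empty timeline.
    """
    if track.n_frames < window_spec.width:
        return []
    signals = derive_signals(track, spec.channels)
    dummy = FrameLabels(track.participant_id, np.zeros(track.n_frames, dtype=int))
    samples = window_dataset(signals, dummy, window_spec)
    table = extract_features(samples, spec)
    X, _, _, _ = split_features(table)
    preds = model.predict(X)
    timeline = []
    run_start = run_end = run_label = None
    for w, label in zip(samples, preds):
        if label == run_label and run_end is not None and w.start <= run_end:
            run_end = w.end
            continue
        if run_label not in (None, 0):
            timeline.append((run_label, run_start, run_end))
        run_label, run_start, run_end = label, w.start, w.end
    if run_label not in (None, 0):
        timeline.append((run_label, run_start, run_end))
    return [
        {
            "participant": track.participant_id,
            "label": CODE_LABELS[int(label)],
            "start_sec": start / track.frame_rate,
            "end_sec": end / track.frame_rate,
        }
        for label, start, end in timeline
    ]
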