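"""Leave-one-subject-out evaluation, metrics, and time-to-detection analysis.

LOSO cross-validation trains one model per subject on all other subjects'
rows and scores it on the held-out subject; per-subject accuracy and F1 are
then averaged unweighted. Time to detection (TTD) is the span between the
first and last raw sample one classification decision consumes:

    TTD = t_length + (w - 1) * t_step        (seconds)

for window width t_length, window step t_step and sequence window w.

The classifier roster is fixed and deliberately untuned: decision tree
(depth 10), 1-NN, 10-NN, random forests of 10 and 100 trees (depth 10,
balanced class weights), an RBF SVM with balanced class weights, a bagged
SVM (10 bootstrap replicates, majority vote) and AdaBoost over 10 random
forests of 100 trees. Distance- and kernel-based learners (kNN, SVM) get
train-fold standardization; trees are scale-invariant and run on raw
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pipeline import extract_features
from .segmentation import SegmentationConfig
from .signal_io import LabeledSignal, feature_columns

logger = logging.getLogger(__name__)

TASKS = ("binary", "ternary")

#: kinds whose learners are scale-sensitive and get train-fold standardization
_SCALED_KINDS = frozenset({"knn1", "knn10", "svm", "bagsvm"})

CLASSIFIER_KINDS = ("dt", "knn1", "knn10", "rf10", "rf100", "svm", "bagsvm", "adarf", "majority")


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier configuration from the evaluation roster."""

    kind: str = "knn10"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; use one of {CLASSIFIER_KINDS}")


def make_classifier(spec: ClassifierSpec):
    """Build the scikit-learn estimator for a spec (seeded, untuned defaults)."""
    kind, seed, p = spec.kind, spec.seed, spec.params
    if kind == "dt":
        est = DecisionTreeClassifier(max_depth=p.get("depth", 10), random_state=seed)
    elif kind == "knn1":
        est = KNeighborsClassifier(n_neighbors=1)
    elif kind == "knn10":
        est = KNeighborsClassifier(n_neighbors=p.get("k", 10))
    elif kind in ("rf10", "rf100"):
        est = RandomForestClassifier(
            n_estimators=p.get("n_trees", 10 if kind == "rf10" else 100),
            max_depth=p.get("depth", 10),
            class_weight="balanced",
            random_state=seed,
        )
    elif kind == "svm":
        est = SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    elif kind == "bagsvm":
        est = BaggingClassifier(
            estimator=SVC(kernel="rbf", class_weight="balanced"),
            n_estimators=p.get("n_estimators", 10),
            random_state=seed,
        )
    elif kind == "adarf":
        est = AdaBoostClassifier(
            estimator=RandomForestClassifier(
                n_estimators=100, max_depth=10, class_weight="balanced", random_state=seed
            ),
            n_estimators=p.get("n_estimators", 10),
            random_state=seed,
        )
    elif kind == "majority":
        est = DummyClassifier(strategy="most_frequent")
    if kind in _SCALED_KINDS:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class ConfusionCounts:
    """A confusion table over an ordered class list; binary uses stress as positive."""

    matrix: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix must be square over the class list")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def binary(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionCounts":
        """Build from binary counts with stress (code 1) the positive class."""
        return cls(matrix=np.array([[tn, fp], [fn, tp]]), classes=(0, 1))

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes: Sequence) -> "ConfusionCounts":
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            matrix[index[t], index[p]] += 1
        return cls(matrix=matrix, classes=classes)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correct decisions: (TP + TN) / total, i.e. trace / total."""
    if counts.total == 0:
        raise ValueError("cannot score an empty confusion table")
    return float(np.trace(counts.matrix)) / counts.total


def f1(counts: ConfusionCounts, averaging: str = "binary") -> float:
    """F1 = 2TP / (2TP + FP + FN).

    ``binary`` scores stress as the positive class (the last class in a
    two-class table built by :meth:`ConfusionCounts.binary`). ``macro``
    averages one-vs-rest F1 unweighted over classes; a class with
    2TP + FP + FN == 0 contributes 0 with a logged warning.
    """
    m = counts.matrix

    def one_vs_rest(i: int) -> float:
        tp = m[i, i]
        fp = m[:, i].sum() - tp
        fn = m[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        if denom == 0:
            logger.warning("class %r has no positives anywhere; F1 contribution 0", counts.classes[i])
            return 0.0
        return 2 * tp / denom

    if averaging == "binary":
        if len(counts.classes) != 2:
            raise ValueError("binary averaging needs a two-class table")
        positive = counts.classes.index(1) if 1 in counts.classes else 1
        return float(one_vs_rest(positive))
    if averaging == "macro":
        return float(np.mean([one_vs_rest(i) for i in range(len(counts.classes))]))
    raise ValueError(f"unknown averaging {averaging!r}")


def ttd(t_length_seconds: float, t_step_seconds: float, w: int) -> float:
    """Time to detection in seconds: t_length + (w - 1) * t_step."""
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    return float(t_length_seconds + (w - 1) * t_step_seconds)


def make_binary(labels: Sequence) -> np.ndarray:
    """Collapse states to stress (1) vs no stress (0: baseline, amusement)."""
    labels = np.asarray(labels, dtype=object)
    return (labels == "stress").astype(int)


@dataclass
class ScoreReport:
    """Per-subject and averaged LOSO scores plus the configuration echo."""

    task: str
    per_subject: dict[str, dict[str, float]]
    accuracy_mean: float
    f1_mean: float
    config: dict
    ttd_seconds: float | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_subject": self.per_subject,
            "accuracy_mean": self.accuracy_mean,
            "f1_mean": self.f1_mean,
            "config": self.config,
            "ttd_seconds": self.ttd_seconds,
        }


def loso_evaluate(
    features: pd.DataFrame,
    spec: ClassifierSpec = ClassifierSpec(),
    task: str = "binary",
    config_echo: dict | None = None,
) -> ScoreReport:
    """Leave-one-subject-out evaluation of a feature table.

    For each subject, a fresh classifier is trained on every other
    subject's rows and scored on the held-out subject; standardization
    (when the classifier uses it) is fit on the training fold only. Scores
    are averaged unweighted over subjects. Fully seeded and reproducible.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; use one of {TASKS}")
    subjects = list(dict.fromkeys(features["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    cols = feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    if task == "binary":
        y = make_binary(features["label"].to_numpy())
        classes: tuple = (0, 1)
        averaging = "binary"
    else:
        y = features["label"].to_numpy(dtype=object)
        classes = ("baseline", "stress", "amusement")
        averaging = "macro"
    subject_ids = features["subject_id"].to_numpy()

    template = make_classifier(spec)
    per_subject: dict[str, dict[str, float]] = {}
    for subject in subjects:
        test_mask = subject_ids == subject
        model = clone(template)
        model.fit(X[~test_mask], y[~test_mask])
        y_pred = model.predict(X[test_mask])
        counts = ConfusionCounts.from_predictions(y[test_mask], y_pred, classes)
        scores = {"accuracy": accuracy(counts), "f1": f1(counts, averaging)}
        per_subject[str(subject)] = scores
        logger.info(
            "fold %s: train=%d test=%d accuracy=%.4f f1=%.4f",
            subject, int((~test_mask).sum()), int(test_mask.sum()),
            scores["accuracy"], scores["f1"],
        )
    return ScoreReport(
        task=task,
        per_subject=per_subject,
        accuracy_mean=float(np.mean([s["accuracy"] for s in per_subject.values()])),
        f1_mean=float(np.mean([s["f1"] for s in per_subject.values()])),
        config={"classifier": spec.kind, "seed": spec.seed, **(config_echo or {})},
    )


def fixed_ttd_grid(
    signals: Sequence[LabeledSignal],
    ttd_target: float,
    lengths: Iterable[int],
    overlaps: Iterable[int],
    spec: ClassifierSpec = ClassifierSpec(),
    task: str = "binary",
    fs: float = 4.0,
    **extract_kwargs,
) -> pd.DataFrame:
    """Grid search over (t_length, t_overlap) at a fixed time to detection.

    For each cell with t_overlap < t_length the sequence window
    w = (TTD - t_length) / t_step + 1 must come out a positive integer;
    other cells are left empty (NaN scores). Kept cells run the full
    pipeline and LOSO evaluation.
    """
    signals = list(signals)
    rows = []
    for t_length in lengths:
        for t_overlap in overlaps:
            if not 0 <= t_overlap < t_length:
                continue
            t_step = t_length - t_overlap
            w_exact = (ttd_target - t_length / fs) / (t_step / fs) + 1
            w = int(round(w_exact))
            row = {
                "t_length": t_length,
                "t_overlap": t_overlap,
                "w": np.nan,
                "accuracy": np.nan,
                "f1": np.nan,
            }
            if w >= 1 and abs(w_exact - w) < 1e-9:
                table = extract_features(
                    signals, SegmentationConfig(t_length, t_overlap), w=w, **extract_kwargs
                )
                if len(table) and table["subject_id"].nunique() >= 2:
                    report = loso_evaluate(features=table, spec=spec, task=task)
                    row.update(w=w, accuracy=report.accuracy_mean, f1=report.f1_mean)
            rows.append(row)
    return pd.DataFrame(rows)


def window_sweep(
    signals: Sequence[LabeledSignal],
    w_values: Iterable[int] = range(1, 11),
    t_length: int = 48,
    t_overlap: int = 20,
    spec: ClassifierSpec = ClassifierSpec(kind="knn10"),
    task: str = "binary",
    **extract_kwargs,
) -> pd.DataFrame:
    """Accuracy/F1 versus time to detection for a sweep of window sizes w.

    Uses the fixed segmentation (t_length, t_overlap) and pairs each w's
    LOSO scores with its TTD; the result is sorted by TTD.
    """
    signals = list(signals)
    fs = signals[0].fs
    cfg = SegmentationConfig(t_length, t_overlap)
    rows = []
    for w in w_values:
        table = extract_features(signals, cfg, w=w, **extract_kwargs)
        report = loso_evaluate(features=table, spec=spec, task=task)
        rows.append(
            {
                "w": w,
                "ttd_seconds": ttd(t_length / fs, cfg.t_step / fs, w),
                "accuracy": report.accuracy_mean,
                "f1": report.f1_mean,
            }
        )
    return pd.DataFrame(rows).sort_values("ttd_seconds", ignore_index=True)
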