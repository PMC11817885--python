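"""Per-channel Gaussian-kernel SVM with cross-validated predictions.

Classification follows the study protocol: stratified 10-fold
cross-validation, per-fold z-score standardisation fitted on the
training folds, and a soft-margin SVM with Gaussian kernel
``K(x, z) = exp(-||x - z||^2 / sigma^2)`` where the kernel scale
``sigma = 20`` applies to the standardised features and the box
constraint is ``C = 1``.  The out-of-fold predictions are assembled into
one full-length prediction vector per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["PredictionVector", "Metrics", "svm_crossval", "compute_metrics"]


@dataclass
class PredictionVector:
    """Out-of-fold predicted labels of one channel, with its accuracy."""

    labels: np.ndarray
    channel: str
    accuracy: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class Metrics:
    """Confusion counts and the five closed-form metrics.

    ``sen``/``spe``/``pre``/``f1scr`` with a zero denominator are
    reported as 0 and listed in ``zero_division``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    pre: float
    f1scr: float
    positive_class: str
    zero_division: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.acc, "sen": self.sen, "spe": self.spe,
            "pre": self.pre, "f1scr": self.f1scr,
            "positive_class": self.positive_class,
            "zero_division": list(self.zero_division),
        }


def svm_crossval(F_selected, y, folds: int = 10, seed: int = 0,
                 kernel_scale: float = 20.0, box_constraint: float = 1.0,
                 channel: str = "") -> PredictionVector:
    """Out-of-fold SVM predictions under stratified k-fold CV.

    Raises
    ------
    ValueError
        If any class has fewer members than ``folds`` (a training fold
        would miss a class).
    """
    F = np.asarray(F_selected, dtype=float)
    y = np.asarray(y)
    if F.ndim != 2 or F.shape[0] != y.shape[0]:
        raise ValueError("F_selected must be (n_segments, n_features) "
                         "aligned with y")
    if F.shape[0] < folds:
        raise ValueError(f"need at least {folds} segments for {folds}-fold CV")
    classes, counts = np.unique(y, return_counts=True)
    if classes.shape[0] < 2:
        raise ValueError("both classes must be present")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} "
            f"segments, fewer than the {folds} folds; stratification fails")

    gamma = 1.0 / (kernel_scale * kernel_scale)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train_idx, test_idx in splitter.split(F, y):
        clf = make_pipeline(
            StandardScaler(),
            SVC(C=box_constraint, kernel="rbf", gamma=gamma))
        clf.fit(F[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(F[test_idx])
    accuracy = float(np.mean(pred == y))
    return PredictionVector(labels=pred, channel=channel, accuracy=accuracy)


def compute_metrics(pred, y, positive_class: str = "SD") -> Metrics:
    """Confusion counts and acc/sen/spe/pre/F1 from a prediction vector."""
    pred_labels = pred.labels if isinstance(pred, PredictionVector) \
        else np.asarray(pred)
    y = np.asarray(y)
    if pred_labels.shape != y.shape:
        raise ValueError("prediction and label vectors differ in length")
    pos_pred = pred_labels == positive_class
    pos_true = y == positive_class
    tp = int(np.sum(pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))

    zero_division: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            zero_division.append(name)
            return 0.0
        return num / den

    return Metrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=_ratio(tp + tn, tp + tn + fp + fn, "acc"),
        sen=_ratio(tp, tp + fn, "sen"),
        spe=_ratio(tn, tn + fp, "spe"),
        pre=_ratio(tp, tp + fp, "pre"),
        f1scr=_ratio(2 * tp, 2 * tp + fp + fn, "f1scr"),
        positive_class=positive_class,
        zero_division=zero_division,
    )
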