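"""Supervised subtype prediction in topic space.

Samples are represented by their topic mixtures P(topic|sample); a
one-hidden-layer neural network (SGD, cross-entropy, rectified hidden
units) predicts the subtype, with a k-nearest-neighbor vote as baseline.
Evaluation reports accuracy, F1, a confusion matrix and per-class
one-vs-all ROC curves with trapezoid-rule AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, roc_curve
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier


def normalize_design(x) -> np.ndarray:
    """Per-row centering and half-range scaling of the design matrix.

    X̄_ij = (X_ij - mean_j' X_ij') / (0.5 * (max_j' X_ij' - min_j' X_ij')).
    Constant rows cannot be scaled; they map to zeros with a warning.
    Output entries are bounded by 2 in absolute value.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty design matrix")
    mean = x.mean(axis=1, keepdims=True)
    half_range = 0.5 * (x.max(axis=1, keepdims=True) - x.min(axis=1, keepdims=True))
    flat = half_range[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows mapped to zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(half_range > 0, (x - mean) / half_range, 0.0)
    return out


def split(n_or_data, proportions, seed: int = 0):
    """Seeded shuffle + contiguous train/validation/test split of indices.

    ``proportions`` must sum to 1; a non-zero proportion that would yield
    an empty part raises.  Returns three index arrays (disjoint,
    exhaustive).
    """
    n = n_or_data if isinstance(n_or_data, (int, np.integer)) else len(n_or_data)
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cuts = np.floor(np.cumsum(proportions) * n).astype(int)[:-1]
    parts = np.split(order, cuts)
    for part, prop in zip(parts, proportions):
        if prop > 0 and part.size == 0:
            raise ValueError("a requested split part is empty")
    return tuple(parts)


@dataclass
class MLPConfig:
    """Architecture and training settings for the one-hidden-layer model."""

    hidden_units: int = 50
    epochs: int = 200
    learning_rates: tuple[float, ...] = (0.003, 0.01, 0.03)
    seed: int = 0


@dataclass
class TrainedMLP:
    model: MLPClassifier
    classes: np.ndarray
    learning_rate: float
    validation_f1: float

    def predict_proba(self, x) -> np.ndarray:
        return self.model.predict_proba(np.asarray(x, dtype=float))

    def predict(self, x) -> np.ndarray:
        return self.model.predict(np.asarray(x, dtype=float))


def train_mlp(x_train, y_train, x_val=None, y_val=None,
              config: MLPConfig | None = None) -> TrainedMLP:
    """Train the one-hidden-layer classifier with SGD and cross-entropy.

    The learning rate is chosen from a small grid by macro-F1 on the
    validation set (training-set F1 when no validation set is given).
    Deterministic given ``config.seed``.
    """
    cfg = config or MLPConfig()
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    if x_val is None:
        x_val, y_val = x_train, y_train
    best = None
    for lr in cfg.learning_rates:
        model = MLPClassifier(hidden_layer_sizes=(cfg.hidden_units,),
                              activation="relu", solver="sgd",
                              learning_rate_init=lr, max_iter=cfg.epochs,
                              random_state=cfg.seed, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings expected on the grid
            model.fit(x_train, y_train)
        score = f1_score(y_val, model.predict(np.asarray(x_val, dtype=float)),
                         average="macro")
        if best is None or score > best.validation_f1:
            best = TrainedMLP(model, model.classes_, lr, float(score))
    return best


def knn_baseline(x_train, y_train, x_test, k: int = 5) -> np.ndarray:
    """Majority vote among the k euclidean nearest training points.

    Vote ties break toward the class with the smallest mean distance
    among the tied classes' neighbors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    if k > len(x_train):
        raise ValueError("k exceeds the training-set size")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(x_train)
    dist, idx = nn.kneighbors(np.asarray(x_test, dtype=float))
    predictions = []
    for drow, irow in zip(dist, idx):
        votes = pd.Series(y_train[irow]).value_counts()
        top = votes[votes == votes.max()].index
        if len(top) == 1:
            predictions.append(top[0])
        else:
            means = {c: drow[y_train[irow] == c].mean() for c in top}
            predictions.append(min(means, key=lambda c: (means[c], str(c))))
    return np.asarray(predictions)


@dataclass
class ClassifierReport:
    """Test-set evaluation: accuracy, F1, confusion matrix, per-class ROC/AUC."""

    accuracy: float
    f1: float
    confusion: pd.DataFrame
    auc: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "auc": self.auc,
                "confusion": self.confusion.to_dict()}


def evaluate(scores, y_true, classes=None) -> ClassifierReport:
    """Evaluate class-probability scores against true labels.

    ``scores`` is sample x class (columns ordered as ``classes``); a 1-D
    array is treated as the positive-class probability of a binary
    problem.  ROC curves use a threshold sweep per class (one-vs-all),
    AUC the trapezoid rule; the confusion matrix uses argmax (multi-class)
    or a 0.5 threshold (binary); F1 is macro-averaged.  Classes absent
    from the test set get NaN AUC and a warning.
    """
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty test set")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        if classes is None:
            classes = np.unique(y_true)
        if len(classes) != 2:
            raise ValueError("1-D scores require a binary problem")
        scores = np.column_stack([1.0 - scores, scores])
    classes = np.asarray(classes if classes is not None else np.unique(y_true))
    if scores.shape[1] != classes.size:
        raise ValueError("score columns do not match classes")

    binary = classes.size == 2
    if binary:
        y_pred = np.where(scores[:, 1] > 0.5, classes[1], classes[0])
    else:
        y_pred = classes[np.argmax(scores, axis=1)]

    aucs, rocs = {}, {}
    for j, cls in enumerate(classes):
        positive = (y_true == cls).astype(int)
        if positive.sum() == 0 or positive.sum() == positive.size:
            warnings.warn(f"class {cls!r} missing from the test set; ROC undefined")
            aucs[str(cls)] = float("nan")
            continue
        fpr, tpr, _ = roc_curve(positive, scores[:, j])
        aucs[str(cls)] = float(_trapezoid_auc(fpr, tpr))
        rocs[str(cls)] = (fpr, tpr)

    confusion = pd.DataFrame(
        _sk_confusion(y_true, y_pred, labels=classes),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"))
    return ClassifierReport(
        accuracy=float((y_pred == y_true).mean()),
        f1=float(f1_score(y_true, y_pred, average="macro")),
        confusion=confusion,
        auc=aucs,
        roc=rocs,
    )
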