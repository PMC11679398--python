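"""Late (decision-level) fusion of the scalogram and phasogram models.

Strategy S7a averages the two 5-class probability vectors; strategies
S7b–h train a meta-classifier on the concatenated probabilities
(feature layout: 5 scalogram-model probabilities followed by 5
phasogram-model probabilities) with fixed hyperparameters:

    S7b  linear SVM, C = 1
    S7c  decision tree
    S7d  random forest, 500 estimators
    S7e  logistic regression, C = 1
    S7f  Gaussian naive Bayes
    S7g  kNN, k = 11
    S7h  ridge (linear classifier with L2 strength 0.5)

Ties everywhere break to the lowest class index (class order N, S, V,
F, Q).  To avoid leakage, meta-classifier training features should be
out-of-fold predictions on the training split (see
:func:`cross_validated_pairs`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

CLASSES = ("N", "S", "V", "F", "Q")

METHODS = ("mean", "svm", "tree", "forest", "logreg", "nb", "knn", "ridge")


@dataclass
class PredictionPair:
    """Probability outputs of the two single-modality models for one beat."""

    p_scalogram: np.ndarray
    p_phasogram: np.ndarray
    true_class: str | None = None

    def __post_init__(self):
        for v in (self.p_scalogram, self.p_phasogram):
            v = np.asarray(v, dtype=float)
            if v.shape != (5,) or np.any(v < 0) or abs(v.sum() - 1) > 1e-5:
                raise ValueError("each vector must be a 5-class probability "
                                 "distribution")
        self.p_scalogram = np.asarray(self.p_scalogram, dtype=float)
        self.p_phasogram = np.asarray(self.p_phasogram, dtype=float)

    @property
    def features(self) -> np.ndarray:
        return np.concatenate([self.p_scalogram, self.p_phasogram])


def _features(pairs) -> np.ndarray:
    return np.vstack([p.features for p in pairs])


def _argmax_lowest(fused_rows) -> list:
    """Argmax with deterministic lowest-index tie-break (np.argmax keeps
    the first maximum, which is the lowest class index)."""
    return [CLASSES[int(np.argmax(row))] for row in np.atleast_2d(fused_rows)]


def fuse_mean(pair: PredictionPair):
    """S7a: element-wise mean -> (predicted class, fused 5-vector)."""
    fused = 0.5 * (pair.p_scalogram + pair.p_phasogram)
    return _argmax_lowest(fused)[0], fused


def _make_estimator(method, seed):
    if method == "svm":
        return LinearSVC(C=1.0)
    if method == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if method == "forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if method == "logreg":
        return LogisticRegression(C=1.0, max_iter=1000)
    if method == "nb":
        return GaussianNB()
    if method == "knn":
        return KNeighborsClassifier(n_neighbors=11)
    if method == "ridge":
        return RidgeClassifier(alpha=0.5)
    raise ValueError(f"unknown late-fusion method {method!r}")


class Combiner:
    """A fitted meta-classifier over the 10-dim concatenated probabilities."""

    def __init__(self, method, estimator, class_order):
        self.method = method
        self.estimator = estimator
        self.class_order = class_order

    def predict(self, pairs):
        X = _features(pairs)
        if X.shape[1] != 10:
            raise ValueError("pairs must yield 10-dimensional features")
        return list(self.estimator.predict(X))


def train_combiner(method, pairs_with_labels, seed=0) -> Combiner:
    """Fit the S7b–h combiner named by ``method`` on labeled pairs."""
    if method == "mean":
        raise ValueError("the mean rule (S7a) needs no training; "
                         "use fuse_mean")
    y = [p.true_class for p in pairs_with_labels]
    if any(c is None for c in y):
        raise ValueError("all training pairs must carry a true class")
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes to train a combiner")
    est = _make_estimator(method, seed)
    est.fit(_features(pairs_with_labels), y)
    return Combiner(method, est, CLASSES)


def predict_combiner(combiner: Combiner, pairs) -> list:
    """Predicted class symbols, one per pair."""
    return combiner.predict(pairs)


def make_pairs(p_scalogram, p_phasogram, labels=None) -> list:
    """Zip two (n, 5) probability matrices into PredictionPair objects."""
    p1 = np.atleast_2d(np.asarray(p_scalogram, dtype=float))
    p2 = np.atleast_2d(np.asarray(p_phasogram, dtype=float))
    if p1.shape != p2.shape or p1.shape[1] != 5:
        raise ValueError("probability matrices must both be (n, 5)")
    if labels is None:
        labels = [None] * len(p1)
    return [PredictionPair(a, b, c) for a, b, c in zip(p1, p2, labels)]


def cross_validation_folds(labels, n_splits=5, seed=0):
    """Stratified fold indices for out-of-fold meta-training protocols."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))
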