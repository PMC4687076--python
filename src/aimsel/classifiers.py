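"""The four multi-class ancestry classifiers compared by the pipeline.

* ``smo`` — :class:`PairwiseLinearSVM`: a soft-margin linear SVM per
  unordered class pair with one-vs-one voting, features standardised on the
  training data.  The name refers to the model family (the classic SMO
  algorithm trains exactly this model); any convergent SVM optimiser
  satisfies the contract, and the per-pair subproblems here are solved by
  libsvm via scikit-learn.
* ``ib1`` — :class:`OneNearestNeighbor`: 1-NN under per-feature min-max
  normalised Euclidean distance.
* ``dagging`` — :class:`DaggingClassifier`: disjoint equal-size random
  partitions of the training set, one base learner per partition, majority
  vote.
* ``random_forest`` — scikit-learn's RandomForestClassifier with
  sqrt(M) features per split.

Vote ties are broken by the lexicographically smallest label; 1-NN
distance ties by the earliest training index.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils import check_random_state


def _check_X_y(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    return X, y


def _vote(pred_matrix: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Majority vote over rows of shape (n_voters, n_samples); ties go to the
    lexicographically smallest class (classes are sorted)."""
    n_samples = pred_matrix.shape[1]
    counts = np.zeros((len(classes), n_samples), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    for row in pred_matrix:
        for s, p in enumerate(row):
            counts[class_index[p], s] += 1
    return classes[np.argmax(counts, axis=0)]  # argmax: first max = smallest label


class PairwiseLinearSVM(ClassifierMixin, BaseEstimator):
    """One-vs-one linear soft-margin SVM with internal standardisation.

    Parameters
    ----------
    C : float, default=1.0
        Soft-margin penalty shared by all pairwise machines.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X, y = _check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        Z = (X - self.mean_) / self.scale_
        self.machines_ = {}
        for a in range(len(self.classes_)):
            for b in range(a + 1, len(self.classes_)):
                mask = (y == self.classes_[a]) | (y == self.classes_[b])
                svm = SVC(kernel="linear", C=self.C)
                svm.fit(Z[mask], y[mask])
                self.machines_[(a, b)] = svm
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted model")
        Z = (X - self.mean_) / self.scale_
        preds = np.stack([m.predict(Z) for m in self.machines_.values()])
        return _vote(preds, self.classes_)


class OneNearestNeighbor(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbour classifier under min-max normalised Euclidean distance.

    Each feature is rescaled to [0, 1] using the training minimum and range
    (constant features contribute nothing).  Distance ties are broken by the
    earliest training index.
    """

    def fit(self, X, y):
        X, y = _check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        self.X_ = (X - self.min_) / self.range_
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted model")
        Z = (X - self.min_) / self.range_
        D = cdist(Z, self.X_)
        return self.y_[np.argmin(D, axis=1)]  # argmin: first = earliest index


class DaggingClassifier(ClassifierMixin, BaseEstimator):
    """Disjoint-subset voting ensemble (dagging).

    The training set is shuffled and divided into ``k_subsets`` disjoint
    subsets of n = floor(N / k) samples each (the remainder is unused); one
    clone of ``base_estimator`` is fitted per subset and test samples take
    the majority vote.  With ``k_subsets=1`` the ensemble reduces to its
    base learner fitted on the whole training set.
    """

    def __init__(self, base_estimator=None, k_subsets: int = 10, random_state=None):
        self.base_estimator = base_estimator
        self.k_subsets = k_subsets
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        n_each = X.shape[0] // self.k_subsets
        if n_each == 0:
            raise ValueError(
                f"cannot divide {X.shape[0]} samples into {self.k_subsets} subsets"
            )
        rng = check_random_state(self.random_state)
        perm = rng.permutation(X.shape[0])
        base = self.base_estimator if self.base_estimator is not None else PairwiseLinearSVM()
        self.estimators_ = []
        for i in range(self.k_subsets):
            idx = np.sort(perm[i * n_each : (i + 1) * n_each])
            if len(np.unique(y[idx])) < 2:
                raise ValueError(
                    f"dagging subset {i} contains a single class; "
                    "use fewer subsets or more samples"
                )
            self.estimators_.append(clone(base).fit(X[idx], y[idx]))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted model")
        preds = np.stack([est.predict(X) for est in self.estimators_])
        return _vote(preds, self.classes_)


def make_classifier(name: str, seed: int | None = None, **hyper: Any):
    """Construct one of the four benchmark classifiers by name.

    Names: ``smo`` (C), ``ib1``, ``dagging`` (k_subsets, C of the SMO base),
    ``random_forest`` (n_trees).
    """
    name = name.lower()
    if name == "smo":
        return PairwiseLinearSVM(C=hyper.get("C", 1.0))
    if name == "ib1":
        return OneNearestNeighbor()
    if name == "dagging":
        base = hyper.get("base_estimator") or PairwiseLinearSVM(C=hyper.get("C", 1.0))
        return DaggingClassifier(
            base_estimator=base,
            k_subsets=hyper.get("k_subsets", 10),
            random_state=seed,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hyper.get("n_trees", 100),
            max_features="sqrt",
            random_state=seed,
        )
    raise ValueError(f"unknown classifier name: {name!r}")
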