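"""Minimum-redundancy-maximum-relevance SNP ranking by discrete mutual information.

Relevance of a SNP f with the class label c is the plug-in mutual
information D = I(f, c); redundancy with an already-selected set S of size
m is R = (1/m) * sum_{s in S} I(f, s).  The greedy mRMR (MID difference
scheme) selects at each step the candidate maximising D - R; the first
pick maximises relevance alone.  Genotypes are already categorical
(0/1/2 minor-allele counts), so the maximum-likelihood plug-in estimate is
used directly with no binning or small-sample correction.  Reported
quantities are in bits (log2); the selected order is invariant to the
log base since both terms scale by the same constant.

Missing genotypes must be imputed before ranking; :class:`ModalImputer`
fills each SNP's missing calls with the per-SNP modal status learned on
training samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MISSING


def mutual_information(x: Sequence, y: Sequence, base: float = 2.0) -> float:
    """Plug-in mutual information between two discrete vectors.

    Pairs where either member is :data:`MISSING` are excluded.  Symmetric,
    non-negative, and equal to the entropy of x when y == x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.ones(x.shape[0], dtype=bool)
    if np.issubdtype(x.dtype, np.integer):
        keep &= x != MISSING
    if np.issubdtype(y.dtype, np.integer):
        keep &= y != MISSING
    x, y = x[keep], y[keep]
    n = x.shape[0]
    if n == 0:
        raise ValueError("no usable (non-missing) pairs")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / (px[:, None] * py[None, :])[nz]
    return float(np.sum(joint[nz] * np.log(ratio)) / np.log(base))


class ModalImputer(TransformerMixin, BaseEstimator):
    """Impute missing genotype calls with the per-SNP modal status.

    The mode is computed on the fitted (training) samples over non-missing
    calls; ties go to the smallest status, and an all-missing column
    imputes to 0.
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        modes = np.zeros(X.shape[1], dtype=X.dtype)
        for j in range(X.shape[1]):
            col = X[:, j]
            col = col[col != MISSING]
            if col.size:
                vals, counts = np.unique(col, return_counts=True)
                modes[j] = vals[np.argmax(counts)]  # first max = smallest status
        self.modes_ = modes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted imputer")
        out = X.copy()
        miss = out == MISSING
        out[miss] = np.broadcast_to(self.modes_, out.shape)[miss]
        return out


@dataclass
class RankedFeatureList:
    """Ordered mRMR output: a permutation of candidate indices with traces.

    ``order[h]`` is the candidate chosen at step h; ``relevance`` is
    I(f, c) in input order; ``redundancy_at_selection`` / ``score_at_selection``
    are the mean-MI redundancy and the relevance-minus-redundancy objective
    of each chosen SNP at its selection step (redundancy 0 at step 0).
    """

    order: np.ndarray
    relevance: np.ndarray
    redundancy_at_selection: np.ndarray
    score_at_selection: np.ndarray
    rsids: list[str] | None = None

    def top(self, i: int) -> np.ndarray:
        return self.order[:i]


class MRMRRanker(TransformerMixin, BaseEstimator):
    """Greedy mRMR feature ranking (difference scheme, discrete plug-in MI).

    Parameters
    ----------
    n_select : int or None, default=None
        Number of ranking rounds; None ranks every candidate.

    Attributes
    ----------
    ranking_ : ndarray — selected candidate column indices in rank order.
    relevance_ : ndarray — I(f, c) in bits per input column.
    redundancy_at_selection_, score_at_selection_ : ndarray per rank step.
    """

    def __init__(self, n_select: int | None = None):
        self.n_select = n_select

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if X.shape[1] < 1:
            raise ValueError("at least one candidate SNP is required")
        if (X == MISSING).any():
            raise ValueError("missing genotypes present: impute before ranking")
        n_total = X.shape[1]
        n_select = n_total if self.n_select is None else int(self.n_select)
        if n_select > n_total:
            raise ValueError(f"n_select={n_select} exceeds {n_total} candidates")

        relevance = np.array(
            [mutual_information(X[:, j], y) for j in range(n_total)]
        )
        # One-hot encodings of the 3 genotype statuses for fast pairwise MI:
        # joint counts of (a, b) for every candidate vs a selected column are
        # nine matrix-vector products.
        onehot = np.stack([(X == s).astype(np.float64) for s in (0, 1, 2)])
        n = float(X.shape[0])
        log2 = np.log(2.0)

        order: list[int] = []
        red_trace: list[float] = []
        score_trace: list[float] = []
        cum_red = np.zeros(n_total)
        remaining = np.ones(n_total, dtype=bool)
        for step in range(n_select):
            if step == 0:
                score = relevance.copy()
                red = np.zeros(n_total)
            else:
                red = cum_red / step
                score = relevance - red
            score_masked = np.where(remaining, score, -np.inf)
            pick = int(np.argmax(score_masked))  # ties -> lowest column index
            order.append(pick)
            red_trace.append(float(red[pick]))
            score_trace.append(float(score[pick]))
            remaining[pick] = False
            if step == n_select - 1:
                break
            # MI of every column with the picked column, vectorized.
            s = X[:, pick]
            s_onehot = np.stack([(s == v).astype(np.float64) for v in (0, 1, 2)])
            joint = np.einsum("anj,bn->jab", onehot, s_onehot) / n  # (m, 3, 3)
            px = joint.sum(axis=2)
            py = joint.sum(axis=1)
            prod = px[:, :, None] * py[:, None, :]
            nz = joint > 0
            mi = np.zeros(n_total)
            contrib = np.where(nz, joint * np.log(np.where(nz, joint, 1.0) /
                                                  np.where(nz, prod, 1.0)), 0.0)
            mi = contrib.sum(axis=(1, 2)) / log2
            cum_red += mi
        self.ranking_ = np.asarray(order)
        self.relevance_ = relevance
        self.redundancy_at_selection_ = np.asarray(red_trace)
        self.score_at_selection_ = np.asarray(score_trace)
        self.n_features_in_ = n_total
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted ranker")
        return X[:, self.ranking_]


def mrmr_rank(
    X: np.ndarray,
    y: Sequence,
    n_select: int | None = None,
    rsids: Sequence[str] | None = None,
) -> RankedFeatureList:
    """Functional wrapper over :class:`MRMRRanker`."""
    ranker = MRMRRanker(n_select=n_select).fit(np.asarray(X), np.asarray(y))
    return RankedFeatureList(
        order=ranker.ranking_,
        relevance=ranker.relevance_,
        redundancy_at_selection=ranker.redundancy_at_selection_,
        score_at_selection=ranker.score_at_selection_,
        rsids=[rsids[j] for j in ranker.ranking_] if rsids is not None else None,
    )
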