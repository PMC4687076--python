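"""Train/test splitting, accuracy bookkeeping and per-group allele frequencies.

Accuracy follows the per-group / total convention

    Q_i = T_i / N_i          (correct predictions over group size)
    Q   = sum(T_i) / sum(N_i)

so the total accuracy is the group-size-weighted mean of the per-group
accuracies.  Splitting is stratified: each population contributes
round-half-to-even(test_fraction * n_g) samples to the independent test
set, which reproduces the published HapMap-style per-group train/test
counts exactly at a 15% test fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .io import MISSING


class SplitError(ValueError):
    """Raised when a stratified split would leave a group without training samples."""


@dataclass
class SplitSpec:
    """Stratified split specification: per-group test allocation is
    round-half-to-even(test_fraction * group size)."""

    test_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def allocate_test_counts(
    group_sizes: Mapping[str, int], test_fraction: float = 0.15
) -> dict[str, int]:
    """Per-group test-set sizes under exact half-to-even rounding.

    Uses exact rational arithmetic so that e.g. 110 * 0.15 = 16.5 rounds
    to 16 rather than being perturbed by floating point.
    """
    frac = Fraction(test_fraction).limit_denominator(10**6)
    return {g: round(frac * n) for g, n in group_sizes.items()}


def stratified_split(
    labels: Sequence[str], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (train, test) stratified by population.

    Deterministic given ``spec.seed``; groups are processed in sorted label
    order.  Raises :class:`SplitError` if any group's test allocation
    equals its size.
    """
    labels = np.asarray([str(x) for x in labels])
    groups = sorted(set(labels))
    sizes = {g: int((labels == g).sum()) for g in groups}
    if any(n == 0 for n in sizes.values()):
        raise SplitError("every group must be non-empty")
    counts = allocate_test_counts(sizes, spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    test_parts = []
    for g in groups:
        if counts[g] == sizes[g]:
            raise SplitError(
                f"group {g!r}: test allocation {counts[g]} leaves no training samples"
            )
        idx = np.flatnonzero(labels == g)
        test_parts.append(rng.choice(idx, size=counts[g], replace=False))
    test = np.sort(np.concatenate(test_parts)).astype(int) if test_parts else np.array([], dtype=int)
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-group (Q_i) and total (Q) accuracy."""

    confusion: pd.DataFrame  # rows = actual, columns = predicted
    per_group_accuracy: pd.Series
    total_accuracy: float
    n_per_group: pd.Series
    correct_per_group: pd.Series

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "EvaluationReport":
        y_true = np.asarray([str(x) for x in y_true])
        y_pred = np.asarray([str(x) for x in y_pred])
        groups = sorted(set(y_true) | set(y_pred))
        conf = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
        for t, p in zip(y_true, y_pred):
            conf.loc[t, p] += 1
        actual = [g for g in groups if conf.loc[g].sum() > 0]
        n_i = conf.sum(axis=1).loc[actual]
        t_i = pd.Series(np.diag(conf.loc[actual, actual]), index=actual)
        q_i = t_i / n_i
        total = float(t_i.sum() / n_i.sum())
        return cls(conf, q_i, total, n_i, t_i)


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    estimator,
    n_folds: int = 10,
    seed: int = 0,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation; every sample is predicted exactly once.

    ``folds`` may be supplied to reuse one fold assignment across several
    calls (paired comparisons); otherwise StratifiedKFold(shuffle, seed)
    is used.
    """
    X = np.asarray(X)
    y = np.asarray([str(v) for v in y])
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    for train_idx, test_idx in folds:
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(X[test_idx])
    return EvaluationReport.from_predictions(y, y_pred)


def make_folds(
    y: Sequence[str], n_folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignment, reusable across feature-prefix sizes."""
    y = np.asarray([str(v) for v in y])
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise SplitError(
            f"smallest class has {counts.min()} members < {n_folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros((len(y), 1)), y)]


def evaluate_split(
    X: np.ndarray,
    y: Sequence[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    estimator,
) -> EvaluationReport:
    """Fit on the training indices, predict the test indices, report Q_i / Q.

    Train and test index sets must be disjoint.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    X = np.asarray(X)
    y = np.asarray([str(v) for v in y])
    est = clone(estimator)
    est.fit(X[train_idx], y[train_idx])
    return EvaluationReport.from_predictions(y[test_idx], est.predict(X[test_idx]))


@dataclass
class RepetitionSummary:
    """Accuracies over repeated random train/test splits."""

    cv_accuracies: np.ndarray
    test_accuracies: np.ndarray
    chosen_sizes: list[int] = field(default_factory=list)

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracies))

    @property
    def cv_sd(self) -> float:
        return float(np.std(self.cv_accuracies, ddof=1)) if len(self.cv_accuracies) > 1 else 0.0

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_accuracies, ddof=1)) if len(self.test_accuracies) > 1 else 0.0


def repeat_splits(
    X: np.ndarray,
    y: Sequence[str],
    spec: SplitSpec,
    pipeline: Callable[[np.ndarray, Sequence[str], np.ndarray, np.ndarray, int], tuple[float, float, int]],
    n_reps: int = 30,
) -> RepetitionSummary:
    """Repeat the full train/test pipeline over independent stratified splits.

    ``pipeline(X, y, train_idx, test_idx, seed)`` must return
    ``(cv_accuracy, test_accuracy, n_snps_used)`` for one split; see
    :func:`aimsel.pipeline.run_pipeline`.  Split seeds derive from
    ``spec.seed``.  With a single repetition the sd is reported as 0.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s) for s in ss.generate_state(n_reps) % (2**31)]
    cv_accs, test_accs, sizes = [], [], []
    for rep, s in enumerate(seeds):
        try:
            train_idx, test_idx = stratified_split(y, SplitSpec(spec.test_fraction, s))
            cv_acc, test_acc, n_used = pipeline(X, y, train_idx, test_idx, s)
        except Exception as exc:  # annotate with the repetition index
            raise RuntimeError(f"repetition {rep} failed: {exc}") from exc
        cv_accs.append(cv_acc)
        test_accs.append(test_acc)
        sizes.append(n_used)
    return RepetitionSummary(np.asarray(cv_accs), np.asarray(test_accs), sizes)


def minor_allele_frequency(
    values: np.ndarray,
    labels: Sequence[str],
    rsids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group, per-SNP minor allele frequency.

    frequency = (sum of coded genotypes) / (2 x non-missing count in group);
    NaN where a group has no non-missing call at a SNP.
    """
    values = np.asarray(values)
    labels = np.asarray([str(x) for x in labels])
    groups = sorted(set(labels))
    if rsids is None:
        rsids = [f"snp{j}" for j in range(values.shape[1])]
    out = pd.DataFrame(index=groups, columns=list(rsids), dtype=float)
    for g in groups:
        sub = values[labels == g]
        nonmiss = sub != MISSING
        counts = nonmiss.sum(axis=0)
        sums = np.where(nonmiss, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(counts > 0, sums / (2.0 * counts), np.nan)
        out.loc[g] = freq
    return out
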