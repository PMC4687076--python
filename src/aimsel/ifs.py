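"""Incremental feature selection over nested prefixes of a ranked SNP list.

For each prefix size i the top-i ranked SNPs are evaluated by stratified
10-fold cross-validation (fold assignment fixed across all i, so prefix
sizes are compared on identical partitions), tracing total and per-group
accuracy — the IFS curve.  The optimal prefix is either the smallest i
achieving the curve's maximum ("max" mode) or the smallest i whose
accuracy reaches ``theta`` and is never exceeded by more than ``delta`` at
any later evaluated size ("plateau" mode, the reproducible analogue of
picking the point where the curve flattens out above 90%).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, cross_validate, make_folds


@dataclass
class IFSCurve:
    """Per-prefix-size cross-validated accuracies over nested top-i SNP sets."""

    frame: pd.DataFrame  # columns: n_snps, total, then one column per group
    classifier_name: str
    seed: int
    folds: list = field(default_factory=list, repr=False)
    order: np.ndarray | None = None

    @property
    def sizes(self) -> np.ndarray:
        return self.frame["n_snps"].to_numpy()

    @property
    def totals(self) -> np.ndarray:
        return self.frame["total"].to_numpy()

    @property
    def fold_hash(self) -> str:
        """Digest of the fold assignment; equal across prefix sizes by design."""
        h = hashlib.sha256()
        for _, test_idx in self.folds:
            h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        return h.hexdigest()


def run_ifs(
    X: np.ndarray,
    y: Sequence[str],
    order: Sequence[int],
    estimator,
    max_i: int | None = None,
    step: int = 1,
    n_folds: int = 10,
    seed: int = 0,
) -> IFSCurve:
    """Cross-validate nested top-i prefixes of ``order`` (i = step, 2*step, ...).

    The matrix must be complete (imputed).  Fold assignment is computed once
    and reused for every prefix size.
    """
    X = np.asarray(X)
    order = np.asarray(order)
    if max_i is None:
        max_i = len(order)
    if max_i > len(order):
        raise ValueError(f"max_i={max_i} exceeds ranked list length {len(order)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    folds = make_folds(y, n_folds=n_folds, seed=seed)
    rows = []
    reports: list[EvaluationReport] = []
    for i in range(step, max_i + 1, step):
        report = cross_validate(X[:, order[:i]], y, estimator, folds=folds)
        reports.append(report)
        row = {"n_snps": i, "total": report.total_accuracy}
        row.update({g: report.per_group_accuracy[g] for g in report.per_group_accuracy.index})
        rows.append(row)
    curve = IFSCurve(
        frame=pd.DataFrame(rows),
        classifier_name=type(estimator).__name__,
        seed=seed,
        folds=folds,
        order=order,
    )
    curve.reports = reports
    return curve


@dataclass
class OptimalSelection:
    """Result of applying an optimal-prefix rule to an IFS curve."""

    found: bool
    n_snps: int | None
    accuracy: float | None
    indices: np.ndarray | None
    mode: str

    def __bool__(self) -> bool:
        return self.found


def select_optimal(
    curve: IFSCurve,
    mode: str = "plateau",
    theta: float = 0.90,
    delta: float = 0.01,
) -> OptimalSelection:
    """Choose the optimal prefix size from an IFS curve.

    mode="max": smallest evaluated i achieving the maximum total accuracy.
    mode="plateau": smallest i with total accuracy >= theta whose accuracy
    is within delta of everything later on the curve; returns a
    ``found=False`` result if no evaluated size qualifies.
    """
    if len(curve.frame) == 0:
        raise ValueError("empty IFS curve")
    sizes = curve.sizes
    totals = curve.totals
    if mode == "max":
        pos = int(np.argmax(totals))  # first occurrence of the max
    elif mode == "plateau":
        pos = None
        for p in range(len(sizes)):
            later = totals[p + 1 :]
            later_max = later.max() if later.size else -np.inf
            if totals[p] >= theta and later_max <= totals[p] + delta:
                pos = p
                break
        if pos is None:
            return OptimalSelection(False, None, None, None, mode)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = int(sizes[pos])
    indices = curve.order[:n] if curve.order is not None else None
    return OptimalSelection(True, n, float(totals[pos]), indices, mode)
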