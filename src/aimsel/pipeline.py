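"""End-to-end pipeline: filter -> impute -> rank -> (IFS or fixed prefix) -> evaluate.

All data-dependent choices (minor-allele coding aside) are made on the
training slice only: the Cramer's V filter, the modal imputation values,
the mRMR ranking and the IFS curve are computed on training samples, and
the final model is refitted on the whole training set before scoring the
held-out test samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import CramersVFilter
from .classifiers import make_classifier
from .evaluation import EvaluationReport, cross_validate, evaluate_split
from .ifs import IFSCurve, OptimalSelection, run_ifs, select_optimal
from .mrmr import ModalImputer, MRMRRanker


@dataclass
class PipelineConfig:
    """Configuration of one filter->rank->select->evaluate run."""

    filter_threshold: float = 0.6
    classifier: str = "smo"
    classifier_params: dict = field(default_factory=dict)
    n_folds: int = 10
    # Prefix choice: fixed size, or an IFS plateau search when n_keep is None.
    n_keep: int | None = None
    ifs_step: int = 1
    ifs_max_i: int | None = None
    selection_mode: str = "plateau"
    theta: float = 0.90
    delta: float = 0.01


@dataclass
class PipelineResult:
    candidates: np.ndarray
    ranking: np.ndarray  # column indices into the original matrix, rank order
    chosen_n: int
    chosen_indices: np.ndarray
    cv_report: EvaluationReport
    test_report: EvaluationReport
    curve: IFSCurve | None = None
    selection: OptimalSelection | None = None


def run_pipeline(
    X: np.ndarray,
    y: Sequence[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
) -> PipelineResult:
    """Run the full SNP-selection pipeline on one train/test split."""
    X = np.asarray(X)
    y = np.asarray([str(v) for v in y])
    Xtr, ytr = X[train_idx], y[train_idx]

    filt = CramersVFilter(threshold=config.filter_threshold).fit(Xtr, ytr)
    candidates = np.flatnonzero(filt.support_)
    if candidates.size == 0:
        raise RuntimeError("no candidate SNP passed the association filter")

    imputer = ModalImputer().fit(Xtr[:, candidates])
    Ztr = imputer.transform(Xtr[:, candidates])
    Zall = imputer.transform(X[:, candidates])

    ranker = MRMRRanker().fit(Ztr, ytr)
    ranking = candidates[ranker.ranking_]

    clf = make_classifier(config.classifier, seed=seed, **config.classifier_params)
    curve = None
    selection = None
    if config.n_keep is not None:
        chosen_n = min(config.n_keep, len(ranking))
    else:
        max_i = config.ifs_max_i or len(ranking)
        max_i = min(max_i, len(ranking))
        curve = run_ifs(
            Ztr,
            ytr,
            ranker.ranking_,
            clf,
            max_i=max_i,
            step=config.ifs_step,
            n_folds=config.n_folds,
            seed=seed,
        )
        selection = select_optimal(
            curve, mode=config.selection_mode, theta=config.theta, delta=config.delta
        )
        if not selection.found:
            # Fall back to the best evaluated prefix when no plateau qualifies.
            selection = select_optimal(curve, mode="max")
        chosen_n = selection.n_snps
    chosen = ranking[:chosen_n]

    cv_report = cross_validate(
        Ztr[:, ranker.ranking_[:chosen_n]], ytr, clf, n_folds=config.n_folds, seed=seed
    )
    test_report = evaluate_split(
        Zall[:, ranker.ranking_[:chosen_n]], y, train_idx, test_idx, clf
    )
    return PipelineResult(
        candidates=candidates,
        ranking=ranking,
        chosen_n=int(chosen_n),
        chosen_indices=chosen,
        cv_report=cv_report,
        test_report=test_report,
        curve=curve,
        selection=selection,
    )


def make_repeat_pipeline(config: PipelineConfig):
    """Adapter for :func:`aimsel.evaluation.repeat_splits`: returns a callable
    mapping one split to (cv_accuracy, test_accuracy, n_snps_used)."""

    def _run(X, y, train_idx, test_idx, seed):
        res = run_pipeline(X, y, train_idx, test_idx, config, seed=seed)
        return (
            res.cv_report.total_accuracy,
            res.test_report.total_accuracy,
            res.chosen_n,
        )

    return _run
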