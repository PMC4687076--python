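"""Per-SNP Cramer's V association with population labels.

Each SNP's additive genotype status (0/1/2 minor-allele copies) is tabulated
against the population label in a k-groups x r-statuses contingency table;
Pearson's chi-squared on that table, normalised as

    V = sqrt( (chi2 / N) / min(k_eff - 1, r_eff - 1) )

gives an effect size in [0, 1] (0 = no association, 1 = complete
association).  SNPs with V above a threshold (default 0.6, strictly
greater) are retained as ancestry-informative candidates.

Missing calls are excluded per SNP, so N varies by SNP.  k_eff and r_eff
count the groups/statuses actually observed among non-missing calls; a SNP
monomorphic among non-missing calls (r_eff = 1) has V = 0 by definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Observed counts O[i, j] of genotype status j within population i.

    Empty rows (populations with no non-missing call) and empty columns
    (statuses never observed) are dropped at construction.
    """

    O: np.ndarray
    row_labels: list[str]
    col_labels: list[int]

    @property
    def k(self) -> int:
        return self.O.shape[0]

    @property
    def r(self) -> int:
        return self.O.shape[1]

    @property
    def N(self) -> int:
        return int(self.O.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.O.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.O.sum(axis=0)


@dataclass
class AssociationResult:
    rsid: str
    chi_squared: float
    cramers_v: float
    k_eff: int
    r_eff: int
    n_used: int


def contingency_table(
    genotypes: np.ndarray, labels: Sequence[str]
) -> ContingencyTable:
    """Tabulate one SNP column against population labels, excluding missing calls."""
    genotypes = np.asarray(genotypes)
    labels = np.asarray(labels)
    if genotypes.shape[0] != labels.shape[0]:
        raise ValueError("genotypes and labels must have the same length")
    keep = genotypes != MISSING
    if not keep.any():
        raise ValueError("all calls missing: degenerate contingency table")
    g = genotypes[keep]
    lab = labels[keep]
    groups = sorted(set(str(x) for x in np.asarray(labels)))
    statuses = sorted(set(int(x) for x in g))
    gi = {name: i for i, name in enumerate(groups)}
    si = {s: j for j, s in enumerate(statuses)}
    O = np.zeros((len(groups), len(statuses)), dtype=np.int64)
    np.add.at(O, ([gi[str(x)] for x in lab], [si[int(x)] for x in g]), 1)
    # Drop populations with no non-missing call at this SNP.
    nonempty = O.sum(axis=1) > 0
    O = O[nonempty]
    groups = [grp for grp, ok in zip(groups, nonempty) if ok]
    return ContingencyTable(O, groups, statuses)


def chi_squared(table: ContingencyTable) -> float:
    """Pearson's chi-squared statistic of the table (no continuity correction)."""
    if table.r < 2 or table.k < 2:
        return 0.0
    return float(chi2_contingency(table.O, correction=False)[0])


def cramers_v(table: ContingencyTable) -> float:
    """Cramer's V in [0, 1]; 0 if the table is monomorphic (single status)."""
    d = min(table.k - 1, table.r - 1)
    if d < 1:
        return 0.0
    v = np.sqrt(chi_squared(table) / table.N / d)
    return float(min(v, 1.0))


def association_scan(
    values: np.ndarray,
    labels: Sequence[str],
    rsids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vectorized Cramer's V over every SNP column of an additive matrix.

    Returns a DataFrame with columns rsid, chi_squared, cramers_v, k_eff,
    r_eff, n_used, one row per SNP in input order.
    """
    values = np.asarray(values)
    labels = np.asarray([str(x) for x in labels])
    n, m = values.shape
    if labels.shape[0] != n:
        raise ValueError("labels length does not match matrix rows")
    groups = sorted(set(labels))
    k = len(groups)
    # counts[g, s, j]: occurrences of status s in group g at SNP j
    counts = np.zeros((k, 3, m), dtype=np.int64)
    for gi, grp in enumerate(groups):
        sub = values[labels == grp]
        for s in (0, 1, 2):
            counts[gi, s] = (sub == s).sum(axis=0)
    row_tot = counts.sum(axis=1)  # (k, m)
    col_tot = counts.sum(axis=0)  # (3, m)
    N = col_tot.sum(axis=0).astype(float)  # (m,)
    k_eff = (row_tot > 0).sum(axis=0)
    r_eff = (col_tot > 0).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        E = row_tot[:, None, :] * col_tot[None, :, :] / N[None, None, :]
        dev = np.where(E > 0, (counts - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
        chi2 = dev.sum(axis=(0, 1))
        d = np.minimum(k_eff - 1, r_eff - 1).astype(float)
        v = np.sqrt(np.where(d >= 1, chi2 / np.where(N > 0, N, 1.0), 0.0)
                    / np.where(d >= 1, d, 1.0))
    v = np.where((d >= 1) & (N > 0), np.minimum(v, 1.0), 0.0)
    chi2 = np.where(N > 0, chi2, 0.0)
    if rsids is None:
        rsids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "rsid": list(rsids),
            "chi_squared": chi2,
            "cramers_v": v,
            "k_eff": k_eff,
            "r_eff": r_eff,
            "n_used": N.astype(int),
        }
    )


class CramersVFilter(SelectorMixin, BaseEstimator):
    """Feature selector keeping SNPs whose Cramer's V exceeds ``threshold``.

    The filter is strict: a SNP with V exactly equal to the threshold is
    removed.  Fit on training data only when used in a train/test pipeline.

    Parameters
    ----------
    threshold : float, default=0.6
        Minimum (exclusive) Cramer's V for a SNP to be retained.

    Attributes
    ----------
    cramers_v_ : ndarray of shape (n_features,)
    chi_squared_ : ndarray of shape (n_features,)
    n_used_ : ndarray of shape (n_features,)
        Non-missing sample count per SNP.
    support_ : boolean ndarray of shape (n_features,)
    """

    def __init__(self, threshold: float = 0.6):
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        scan = association_scan(X, y)
        self.cramers_v_ = scan["cramers_v"].to_numpy()
        self.chi_squared_ = scan["chi_squared"].to_numpy()
        self.k_eff_ = scan["k_eff"].to_numpy()
        self.r_eff_ = scan["r_eff"].to_numpy()
        self.n_used_ = scan["n_used"].to_numpy()
        self.support_ = self.cramers_v_ > self.threshold
        self.n_features_in_ = X.shape[1]
        if not self.support_.any():
            warnings.warn(
                f"no SNP passed the Cramer's V > {self.threshold} filter",
                stacklevel=2,
            )
        return self

    def _get_support_mask(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise AttributeError("CramersVFilter is not fitted")
        return self.support_

    def __sklearn_check_is_fitted__(self):  # pragma: no cover
        return hasattr(self, "support_")


def filter_snps(
    matrix: GenotypeMatrix | np.ndarray,
    labels: Sequence[str],
    threshold: float = 0.6,
) -> tuple[list[int], pd.DataFrame]:
    """Candidate SNP indices (V strictly > threshold, genomic order) plus the
    full per-SNP association table with a ``pass`` flag."""
    if isinstance(matrix, GenotypeMatrix):
        values, rsids = matrix.values, matrix.rsids
    else:
        values, rsids = np.asarray(matrix), None
    scan = association_scan(values, labels, rsids)
    scan["pass"] = scan["cramers_v"] > threshold
    candidates = list(np.flatnonzero(scan["pass"].to_numpy()))
    if not candidates:
        warnings.warn(f"no SNP passed the Cramer's V > {threshold} filter", stacklevel=2)
    return candidates, scan
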