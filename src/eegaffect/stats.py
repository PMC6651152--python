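"""Friedman rank comparison of paired method accuracies.

Given N paired comparisons of k methods (here: the per-split accuracies
produced by the evaluation protocols), methods are ranked within each
comparison (rank 1 = highest accuracy, ties averaged) and the Friedman
chi-square statistic with tie correction is referred to a chi-square
distribution with k-1 degrees of freedom.  Lower average rank = better
method.

The tie-corrected statistic is

    chi2 = (k-1) * (sum_j R_j^2 - N^2 k (k+1)^2 / 4)
           / (sum_ij r_ij^2 - N k (k+1)^2 / 4)

with r_ij the within-comparison ranks and R_j their column sums; without
ties it reduces to the classical 12/(Nk(k+1)) sum R_j^2 - 3N(k+1).  The
Iman-Davenport F correction is available as an option.

This module implements the test directly because the comparison of
interest has k=2 methods, which general-purpose Friedman routines (e.g.
scipy's) refuse; at k=2 the test is closely related to a sign test, which
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .evaluation import ComparisonRecord

__all__ = ["RankSummary", "friedman", "records_matrix", "friedman_from_records"]


@dataclass
class RankSummary:
    """Average ranks, statistic and p-value of one Friedman comparison."""

    method_names: list[str]
    avg_ranks: np.ndarray
    n_comparisons: int
    statistic: float
    p_value: float
    iman_davenport: bool = False

    def best_method(self) -> str:
        return self.method_names[int(np.argmin(self.avg_ranks))]


def friedman(
    acc: np.ndarray,
    method_names: list[str] | None = None,
    iman_davenport: bool = False,
) -> RankSummary:
    """Friedman test over an N x k matrix of paired accuracies.

    Within each row, methods are ranked by accuracy descending (rank 1 is
    the best; ties receive the average of the ranks they span).  Missing
    cells are rejected rather than imputed.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2:
        raise ValueError("accuracy matrix must be 2-D (comparisons x methods)")
    n, k = acc.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 comparisons and 2 methods")
    if np.isnan(acc).any():
        raise ValueError("missing cells in the accuracy matrix; no imputation")
    if method_names is None:
        method_names = [f"method_{j}" for j in range(k)]
    if len(method_names) != k:
        raise ValueError("method_names length must match the method axis")

    # rank 1 = highest accuracy within each comparison
    ranks = _st.rankdata(-acc, axis=1, method="average")
    col_sums = ranks.sum(axis=0)
    avg_ranks = col_sums / n

    center = n * k * (k + 1) ** 2 / 4.0
    denom = float((ranks**2).sum() - center)
    numer = (k - 1) * float((col_sums**2).sum() - n * center)
    if denom <= 0:  # every comparison fully tied
        stat, p = 0.0, 1.0
    else:
        stat = numer / denom
        if iman_davenport:
            if n * (k - 1) - stat <= 0:
                p = 0.0
            else:
                f_stat = (n - 1) * stat / (n * (k - 1) - stat)
                p = float(_st.f.sf(f_stat, k - 1, (n - 1) * (k - 1)))
                stat = f_stat
        else:
            p = float(_st.chi2.sf(stat, k - 1))
    return RankSummary(
        method_names=list(method_names),
        avg_ranks=avg_ranks,
        n_comparisons=n,
        statistic=float(stat),
        p_value=p,
        iman_davenport=iman_davenport,
    )


def records_matrix(
    records: list[ComparisonRecord],
    methods: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack paired record accuracies into an N x k matrix.

    Every record must carry an accuracy for every requested method.
    """
    if not records:
        raise ValueError("no records")
    if methods is None:
        methods = list(records[0].accuracies)
    rows = []
    for i, rec in enumerate(records):
        missing = [m for m in methods if m not in rec.accuracies]
        if missing:
            raise ValueError(f"record {i} lacks accuracies for {missing}")
        rows.append([rec.accuracies[m] for m in methods])
    return np.array(rows, dtype=float), list(methods)


def friedman_from_records(
    records: list[ComparisonRecord],
    methods: list[str] | None = None,
    iman_davenport: bool = False,
) -> RankSummary:
    """Run the Friedman comparison on a list of paired records."""
    acc, names = records_matrix(records, methods)
    return friedman(acc, names, iman_davenport=iman_davenport)
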