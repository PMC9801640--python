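"""Nonparametric comparison of algorithms over a metric-by-algorithm table.

Two procedures operate on a :class:`ResultsTable` (N metric rows by k
algorithm columns):

* pairwise Wilcoxon signed-rank: differences ranked by absolute value with
  tied ranks averaged, signed rank sums R+ and R-, statistic
  T = min(R+, R-), decision against an embedded small-sample critical-value
  table (no large-sample normal approximation);
* Friedman: per-row ranks (best value rank 1, ties averaged), average rank
  R_j per algorithm, then

      chi2_F = 12N / (k(k+1)) * [ sum_j R_j^2  -  k(k+1)^2 / 4 ]
      F_F    = (N-1) chi2_F / ( N(k-1) - chi2_F )

  with F_F compared against the F distribution at (k-1, (k-1)(N-1)) degrees
  of freedom.

Two critical-value conventions are embedded for the Wilcoxon decision.  The
benchmark protocol this package mirrors rejects at T <= 2 for six paired
values at alpha = 0.05 — the one-sided table — while the standard two-sided
table gives 0 there.  Both decisions are always computed;
``follow_paper=True`` (default) selects the former.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata

__all__ = ["ResultsTable", "WilcoxonResult", "FriedmanResult",
           "wilcoxon_signed_rank", "average_ranks", "friedman",
           "friedman_from_ranks", "compare_all"]

# Wilcoxon signed-rank critical values for T = min(R+, R-), alpha = 0.05.
# Reject when T <= value.  None: no rejection possible at that n.
_CRIT_ONE_SIDED = {5: 0, 6: 2, 7: 3, 8: 5, 9: 8, 10: 10, 11: 13, 12: 17,
                   13: 21, 14: 25, 15: 30, 16: 35, 17: 41, 18: 47, 19: 53,
                   20: 60, 21: 67, 22: 75, 23: 83, 24: 91, 25: 100}
_CRIT_TWO_SIDED = {6: 0, 7: 2, 8: 3, 9: 5, 10: 8, 11: 10, 12: 13, 13: 17,
                   14: 21, 15: 25, 16: 29, 17: 34, 18: 40, 19: 46, 20: 52,
                   21: 58, 22: 65, 23: 73, 24: 81, 25: 89}
# F critical value printed in the benchmark protocol for its k=12, N=6 table
PAPER_F_THRESHOLD = 1.917


class ResultsTable:
    """N evaluation indexes (rows) by k algorithms (columns)."""

    def __init__(self, values, row_names=None, column_names=None):
        if isinstance(values, pd.DataFrame):
            self.df = values.astype(float)
        else:
            self.df = pd.DataFrame(np.asarray(values, dtype=float),
                                   index=row_names, columns=column_names)
        if self.df.isna().any().any():
            raise ValueError("results table has missing cells")

    @property
    def n_indexes(self) -> int:
        return self.df.shape[0]

    @property
    def n_algorithms(self) -> int:
        return self.df.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def drop(self, column: str) -> "ResultsTable":
        return ResultsTable(self.df.drop(columns=[column]))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="Metric")

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls(pd.read_csv(path, index_col=0))

    def __eq__(self, other) -> bool:
        return isinstance(other, ResultsTable) and self.df.equals(other.df)


@dataclass
class WilcoxonResult:
    R_plus: float
    R_minus: float
    T_stat: float
    n_effective: int
    alpha: float
    threshold: Optional[int]
    threshold_standard: Optional[int]
    reject: bool
    reject_standard: bool
    follow_paper: bool
    all_zero: bool = False
    selected: Optional[str] = None


@dataclass
class FriedmanResult:
    rank_matrix: np.ndarray
    average_ranks: "pd.Series"
    chi2: float
    F: float
    df_between: int
    df_error: int
    alpha: float
    critical_value: float
    reject: bool
    paper_threshold: float = PAPER_F_THRESHOLD
    reject_paper_threshold: bool = False
    rank_precision: Optional[int] = 2
    chi2_exact: float = field(default=np.nan)


def wilcoxon_signed_rank(a, b, alpha: float = 0.05,
                         follow_paper: bool = True,
                         names: tuple = ("a", "b")) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of a against b.

    Zero differences are dropped; absolute differences are ranked ascending
    with tied ranks averaged; R+ sums the ranks of positive (a > b)
    differences.  The decision compares T = min(R+, R-) with the embedded
    critical table; ``selected`` names the winner when the null is rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 critical tables are embedded")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0.0, 0, alpha, None, None,
                              False, False, follow_paper, all_zero=True)
    ranks = rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    t = min(r_plus, r_minus)
    thr_paper = _CRIT_ONE_SIDED.get(n)
    thr_std = _CRIT_TWO_SIDED.get(n)
    rej_paper = thr_paper is not None and t <= thr_paper
    rej_std = thr_std is not None and t <= thr_std
    reject = rej_paper if follow_paper else rej_std
    selected = None
    if reject:
        selected = names[0] if r_plus >= r_minus else names[1]
    return WilcoxonResult(r_plus, r_minus, t, n, alpha,
                          thr_paper if follow_paper else thr_std,
                          thr_std, reject, rej_std, follow_paper,
                          selected=selected)


def average_ranks(t: ResultsTable, higher_is_better: bool = True) -> pd.Series:
    """Average rank per algorithm; the best value in a row gets rank 1."""
    vals = t.values
    sign = -1.0 if higher_is_better else 1.0
    ranks = np.vstack([rankdata(sign * row) for row in vals])
    return pd.Series(ranks.mean(axis=0), index=t.df.columns)


def _rank_matrix(t: ResultsTable, higher_is_better: bool) -> np.ndarray:
    sign = -1.0 if higher_is_better else 1.0
    return np.vstack([rankdata(sign * row) for row in t.values])


def friedman_from_ranks(avg_ranks, n_indexes: int, alpha: float = 0.05,
                        k: Optional[int] = None,
                        stat_precision: Optional[int] = 2) -> FriedmanResult:
    """Friedman chi-square and F from a vector of average ranks.

    ``stat_precision`` rounds the chi-square to that many decimals before
    the F transform, matching write-ups that plug the printed two-decimal
    chi-square into the F formula; ``None`` keeps exact arithmetic.
    """
    R = np.asarray(avg_ranks, dtype=float)
    k = len(R) if k is None else k
    N = int(n_indexes)
    chi2_exact = 12.0 * N / (k * (k + 1)) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0)
    chi2 = chi2_exact if stat_precision is None else round(chi2_exact, stat_precision)
    denom = N * (k - 1) - chi2
    F = np.inf if denom <= 0 else (N - 1) * chi2 / denom
    df1, df2 = k - 1, (k - 1) * (N - 1)
    crit = float(f_dist.ppf(1 - alpha, df1, df2))
    idx = avg_ranks.index if isinstance(avg_ranks, pd.Series) else None
    return FriedmanResult(
        rank_matrix=np.empty((0, k)),
        average_ranks=pd.Series(R, index=idx),
        chi2=float(chi2), F=float(F), df_between=df1, df_error=df2,
        alpha=alpha, critical_value=crit,
        reject=bool(F > crit),
        reject_paper_threshold=bool(F > PAPER_F_THRESHOLD),
        rank_precision=None, chi2_exact=float(chi2_exact))


def friedman(t: ResultsTable, alpha: float = 0.05,
             higher_is_better: bool = True,
             rank_precision: Optional[int] = 2,
             stat_precision: Optional[int] = 2) -> FriedmanResult:
    """Friedman test over all columns of a results table.

    ``rank_precision`` rounds the average ranks to that many decimals before
    they are squared, and ``stat_precision`` rounds the chi-square before
    the F transform — together they mirror how benchmark write-ups print and
    then reuse two-decimal intermediates; pass ``None`` for exact arithmetic
    (the exact chi-square is always reported as ``chi2_exact``).
    """
    if t.n_indexes < 2 or t.n_algorithms < 2:
        raise ValueError("Friedman needs at least 2 rows and 2 columns")
    ranks = _rank_matrix(t, higher_is_better)
    R_exact = ranks.mean(axis=0)
    N, k = ranks.shape
    exact = friedman_from_ranks(R_exact, N, alpha=alpha, stat_precision=None)
    R_used = R_exact if rank_precision is None else np.round(R_exact, rank_precision)
    res = friedman_from_ranks(pd.Series(R_used, index=t.df.columns), N,
                              alpha=alpha, stat_precision=stat_precision)
    res.rank_matrix = ranks
    res.rank_precision = rank_precision
    res.chi2_exact = exact.chi2
    res.average_ranks = pd.Series(R_exact, index=t.df.columns)
    return res


def compare_all(t: ResultsTable, baseline: str, alpha: float = 0.05,
                follow_paper: bool = True) -> pd.DataFrame:
    """Wilcoxon of one column against every other; one row per opponent.

    Returns a frame with columns R+, R-, T, Hypothesis, Selected, matching
    the layout of pairwise benchmark comparison tables.
    """
    if baseline not in t.df.columns:
        raise ValueError(f"unknown baseline column {baseline!r}")
    rows = {}
    for col in t.df.columns:
        if col == baseline:
            continue
        res = wilcoxon_signed_rank(t.df[baseline].to_numpy(),
                                   t.df[col].to_numpy(), alpha=alpha,
                                   follow_paper=follow_paper,
                                   names=(baseline, col))
        rows[col] = {
            "R+": res.R_plus, "R-": res.R_minus, "T": res.T_stat,
            "Hypothesis": "Rejected" if res.reject else "Accepted",
            "Selected": res.selected if res.selected else "-",
        }
    return pd.DataFrame(rows).T
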