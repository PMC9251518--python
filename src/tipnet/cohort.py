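"""Baseline-characteristics statistics for staged cohorts.

Continuous covariates reported as group mean +/- SD are compared by one-way
ANOVA reconstructed from the summaries alone; categorical covariates by the
Pearson chi-square test or the Freeman-Halton generalisation of Fisher's
exact test to r x c tables (full enumeration of all tables with the observed
margins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "anova_from_summary",
    "fisher_exact_rxc",
    "chi_square_test",
]


@dataclass
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]

    def check_margins(self) -> None:
        if (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all row and column margins must be positive")


def anova_from_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df1, df2, p) from per-group mean/SD/n.

    Between-group sum of squares uses the size-weighted grand mean; the
    within-group mean square pools the (n-1)-weighted group variances. When
    every group variance is zero the test degenerates: p = 1 if the means
    agree, p = 0 otherwise.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    ns = np.array([g.n for g in groups], dtype=float)
    k = len(groups)
    N = ns.sum()
    df1, df2 = k - 1, int(N - k)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    msw = ((ns - 1) * sds**2).sum() / (N - k)
    if msw == 0:
        if np.allclose(means, means[0]):
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = (ssb / df1) / msw
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    # multivariate hypergeometric: prod(R_i!) prod(C_j!) / (N! prod(n_ij!))
    return log_margin_const - sum(lgamma(v + 1) for v in table.flat)


def fisher_exact_rxc(
    table: ContingencyTable, max_tables: int = 2_000_000
) -> float:
    """Freeman-Halton exact p for an r x c table.

    Enumerates every table with the observed margins; the p-value is the total
    probability of tables no more probable than the observed one. The "no more
    probable" comparison uses a relative tolerance of 1e-12 so that tables
    tied with the observed probability (common in small balanced designs) are
    counted rather than lost to floating-point noise.
    """
    table.check_margins()
    obs = table.counts
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    N = int(obs.sum())
    log_margin_const = (
        sum(lgamma(r + 1) for r in row_sums)
        + sum(lgamma(c + 1) for c in col_sums)
        - lgamma(N + 1)
    )
    log_p_obs = _log_table_prob(obs, log_margin_const)
    cutoff = log_p_obs + 1e-12 * abs(log_p_obs) + 1e-300

    r, c = obs.shape
    counter = {"tables": 0}
    p_total = 0.0

    def fill_row(i: int, remaining_cols: tuple[int, ...], log_acc: float) -> float:
        counter["tables"] += 1
        if counter["tables"] > max_tables:
            raise ValueError(
                f"enumeration exceeds {max_tables} partial tables; "
                "use chi_square_test for this table"
            )
        if i == r - 1:
            # last row forced by the column margins
            log_p = log_acc - sum(lgamma(v + 1) for v in remaining_cols)
            return np.exp(log_p) if log_p <= cutoff else 0.0
        total = 0.0
        row_n = int(row_sums[i])

        def fill_cell(j: int, left_in_row: int, cols: list[int], acc: float) -> None:
            nonlocal total
            if j == c - 1:
                if left_in_row <= cols[j]:
                    new_cols = list(cols)
                    new_cols[j] -= left_in_row
                    total += fill_row(
                        i + 1, tuple(new_cols), acc - lgamma(left_in_row + 1)
                    )
                return
            hi = min(left_in_row, cols[j])
            for v in range(hi + 1):
                new_cols = list(cols)
                new_cols[j] -= v
                fill_cell(j + 1, left_in_row - v, new_cols, acc - lgamma(v + 1))

        fill_cell(0, row_n, list(remaining_cols), log_acc)
        return total

    base = log_margin_const
    p_total = fill_row(0, tuple(int(v) for v in col_sums), base)
    return float(min(p_total, 1.0))


def chi_square_test(
    table: ContingencyTable, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square (statistic, df, p); continuity correction off by
    default. Errors on a zero expected cell."""
    table.check_margins()
    expected = stats.contingency.expected_freq(table.counts)
    if (expected == 0).any():
        raise ValueError("zero expected cell count; chi-square undefined")
    statistic, p, df, _ = stats.chi2_contingency(table.counts, correction=correction)
    return float(statistic), int(df), float(p)
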