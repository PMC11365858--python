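"""Group-comparison statistics for labelled cohort tables.

Two-group continuous comparisons follow the testing policy used in the
source tables: a normality gate per group, then for normal data an F-test
on the variances deciding between the pooled (Student) and Welch t-test,
otherwise a Mann-Whitney U test with midrank tie correction.  All p-values
are two-sided; no multiple-testing correction is applied (comparisons are
reported per-test).  Categorical tables use the Pearson chi-square without
continuity correction; monotone association uses Spearman's rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestPolicy", "GroupComparison", "compare_groups", "spearman_corr",
           "chi_square_counts"]


@dataclass(frozen=True)
class TestPolicy:
    """Branch configuration for :func:`compare_groups`.

    ``force`` overrides the gates entirely (``"welch_t"``, ``"student_t"``
    or ``"mann_whitney_u"``), so any published table can be reproduced
    under either branch.  The normality gate is Shapiro-Wilk per group at
    ``normality_alpha``; the variance gate is a two-sided F-test at
    ``variance_alpha``.
    """

    normality_alpha: float = 0.05
    variance_alpha: float = 0.05
    force: str | None = None


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _summaries(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(med), "q1": float(q1), "q3": float(q3), "n": int(v.size)}


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or (va >= vb and vb > 0):
        f, d1, d2 = va / vb, a.size - 1, b.size - 1
    else:
        f, d1, d2 = vb / va, b.size - 1, a.size - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, d1, d2)))


def compare_groups(values_a, values_b, policy: TestPolicy = TestPolicy()) -> GroupComparison:
    """Two-sided two-group comparison under the configured policy.

    Returns the chosen test's name, statistic and p-value together with
    per-group summaries computed from the same records.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations "
                         "(parametric and rank branches alike)")

    test = policy.force
    if test is None:
        normal = True
        for v in (a, b):
            if v.size >= 3 and np.ptp(v) > 0:
                if sps.shapiro(v).pvalue < policy.normality_alpha:
                    normal = False
        if normal:
            equal_var = _f_test_p(a, b) >= policy.variance_alpha
            test = "student_t" if equal_var else "welch_t"
        else:
            test = "mann_whitney_u"

    if test == "student_t":
        res = sps.ttest_ind(a, b, equal_var=True)
    elif test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney_u":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test_name=test, statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
                           summary_a=_summaries(a), summary_b=_summaries(b))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties), two-sided p.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def chi_square_counts(table) -> GroupComparison:
    """Pearson chi-square on an r x c count table (no continuity correction).

    df = (r-1)(c-1); zero-margin rows/columns and tables without at least
    2 rows and 2 columns are rejected.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return GroupComparison(test_name="chi_square", statistic=float(stat),
                           p_value=float(p), n_a=int(t.sum()), n_b=int(t.sum()),
                           summary_a={"df": int(dof)})
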