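"""The statistical battery: normality screen, t-tests and RM-ANOVA.

Thin, explicit wrappers over scipy/statsmodels that return a uniform
:class:`TestResult` carrying the statistic, degrees of freedom, two-tailed p
and — for post-hoc comparisons — the adjustment method actually applied
(Holm–Šídák by default, always printed beside adjusted p-values).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "dagostino_pearson",
    "paired_t",
    "unpaired_t",
    "rm_anova",
]

ALPHA = 0.05  # reporting significance level


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    n: int
    applicable: bool = True
    adjusted: bool = False
    method: str | None = None

    @property
    def significant(self) -> bool:
        return self.applicable and self.p < ALPHA


def dagostino_pearson(x) -> TestResult:
    """Omnibus K² normality test (combined skewness + kurtosis, chi² df=2).

    Below n = 8 the K² approximation is invalid and the result is returned
    as inapplicable rather than as a number.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        return TestResult(
            test="dagostino_pearson", statistic=math.nan, df=2, p=math.nan,
            n=n, applicable=False,
        )
    k2, p = sps.normaltest(x)
    return TestResult(
        test="dagostino_pearson", statistic=float(k2), df=2, p=float(p), n=n
    )


def _t_result(name: str, t: float, p: float, df: float, n: int) -> TestResult:
    return TestResult(test=name, statistic=float(t), df=float(df), p=float(p), n=n)


def paired_t(x, y) -> TestResult:
    """Classical paired Student's t on the differences, two-tailed.

    Identical samples give t = 0, p = 1; zero-variance differences with a
    non-zero mean (an infinite t) are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    diff = x - y
    if float(diff.std(ddof=1)) == 0.0:
        if float(diff.mean()) == 0.0:
            return _t_result("paired_t", 0.0, 1.0, n - 1, n)
        raise ValueError("zero-variance differences with non-zero mean: t is undefined")
    t, p = sps.ttest_rel(x, y)
    return _t_result("paired_t", t, p, n - 1, n)


def unpaired_t(x, y) -> TestResult:
    """Two-sample Student's t (equal variances), two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired t requires n >= 2 per group")
    if np.array_equal(x, y):
        return _t_result("unpaired_t", 0.0, 1.0, x.size + y.size - 2, x.size + y.size)
    t, p = sps.ttest_ind(x, y)
    return _t_result("unpaired_t", t, p, x.size + y.size - 2, x.size + y.size)


def rm_anova(
    values: pd.DataFrame, adjust: str = "holm-sidak"
) -> tuple[TestResult, list[TestResult]]:
    """One-way repeated-measures ANOVA with adjusted post-hoc paired t-tests.

    ``values`` has one row per subject and one column per condition; the
    design must be complete (no missing cells).  Returns the omnibus F plus
    one adjusted pairwise comparison per condition pair, each labelled with
    the adjustment method.
    """
    if values.isna().to_numpy().any():
        raise ValueError("missing cells: repeated-measures design must be complete")
    n_subj, n_cond = values.shape
    if n_cond < 2 or n_subj < 2:
        raise ValueError("need >= 2 conditions and >= 2 subjects")

    cond_means = values.mean(axis=0).to_numpy()
    grand = float(values.to_numpy().mean())
    ss_cond = n_subj * float(np.sum((cond_means - grand) ** 2))
    scale = max(float(np.abs(values.to_numpy()).max()), 1.0)
    df_num, df_den = n_cond - 1, (n_subj - 1) * (n_cond - 1)

    if ss_cond < 1e-12 * scale**2:
        omnibus = TestResult(
            test="rm_anova", statistic=0.0, df=(df_num, df_den), p=1.0, n=n_subj
        )
    else:
        long = values.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value"
        )
        table = AnovaRM(long, "value", "subject", within=["condition"]).fit().anova_table
        omnibus = TestResult(
            test="rm_anova",
            statistic=float(table["F Value"].iloc[0]),
            df=(float(table["Num DF"].iloc[0]), float(table["Den DF"].iloc[0])),
            p=float(table["Pr > F"].iloc[0]),
            n=n_subj,
        )

    pairs = list(itertools.combinations(values.columns, 2))
    raw = [paired_t(values[a], values[b]) for a, b in pairs]
    with np.errstate(divide="ignore"):  # p = 1 exactly is fine
        adj_p = multipletests([r.p for r in raw], method=adjust)[1]
    posthoc = [
        TestResult(
            test=f"paired_t[{a} vs {b}]",
            statistic=r.statistic,
            df=r.df,
            p=float(p),
            n=r.n,
            adjusted=True,
            method=adjust,
        )
        for (a, b), r, p in zip(pairs, raw, adj_p)
    ]
    return omnibus, posthoc
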