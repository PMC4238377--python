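"""Between-group comparisons with the study's significance convention.

Rank tests are used for count-derived comparisons (Mann-Whitney for two
groups, Kruskal-Wallis for three or more) and a two-sample t test (Welch by
default) for soma diameters.  All alternatives are two-sided, no
multiple-testing correction is applied, and a comparison is called
significant when p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

ALPHA = 0.05
#: Use the exact Mann-Whitney null when the product of sample sizes is at
#: most this and the pooled data carry no ties; normal approximation with tie
#: correction otherwise.
EXACT_MW_MAX_PRODUCT = 400


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str = ""
    df: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "method": self.method,
            "df": self.df,
            "significant": self.significant,
        }


def mann_whitney(sample_a, sample_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is enumerated for small, tie-free samples
    (n_a * n_b <= 400); otherwise the normal approximation with tie and
    continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= EXACT_MW_MAX_PRODUCT) and not ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(len(a), len(b)),
        method=method,
    )


def kruskal_wallis(*samples) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df).

    Requires at least three nonempty groups; two-group comparisons belong to
    :func:`mann_whitney`.
    """
    if len(samples) == 1 and not np.isscalar(samples[0][0]):
        samples = tuple(samples[0])
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 3:
        raise DomainError("kruskal_wallis needs >= 3 groups; use mann_whitney for two")
    if any(len(g) == 0 for g in groups):
        raise DomainError("all groups must be nonempty")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # degenerate identical groups: H = 0, no evidence against the null
        return GroupComparison(
            test="kruskal_wallis", statistic=0.0, p_value=1.0,
            n=tuple(len(g) for g in groups), df=float(len(groups) - 1),
        )
    res = stats.kruskal(*groups)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=tuple(len(g) for g in groups),
        df=float(len(groups) - 1),
    )


def t_test(sample_a, sample_b, equal_variance: bool = False) -> GroupComparison:
    """Two-sided two-sample t test (Welch by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("t test requires at least 2 values per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison(
                test="t_test", statistic=0.0, p_value=1.0, n=(len(a), len(b)),
                method="equal_var" if equal_variance else "welch",
            )
        raise DomainError("both samples have zero variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return GroupComparison(
        test="t_test",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        method="equal_var" if equal_variance else "welch",
        df=float(res.df),
    )
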