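"""Closed-form statistics from printed summary data.

One-sample t from (mean, SD, n), one-way ANOVA from per-group
(n, mean, SD) triples, and the 2x2 Pearson chi-square from counts.  These
reproduce a study's demographic/behavioral tables without raw data and
double as oracles for the voxelwise machinery (the voxelwise tests must
agree with them on any per-voxel summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupSummary",
    "Crosstab2x2",
    "one_sample_t",
    "oneway_anova_summary",
    "chisq_2x2",
    "two_sample_t_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class Crosstab2x2:
    """Counts (a, b) = row 1, (c, d) = row 2; rows = groups, cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def one_sample_t(mean: float, sd: float, n: int) -> tuple[float, int]:
    """t = mean / (sd / sqrt(n)) against 0, df = n - 1."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(mean / (sd / np.sqrt(n))), n - 1


def oneway_anova_summary(groups: list[GroupSummary]) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group (n, mean, sd); df = (k-1, N-k).

    SSB uses the n-weighted grand mean; MSW pools the within-group variances.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N, k = ns.sum(), len(groups)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    msw = ((ns - 1) * sds**2).sum() / (N - k)
    if msw == 0:
        if ssb == 0:
            raise ValueError("all groups identical and constant; F undefined")
        return float("inf"), k - 1, int(N - k)
    return float((ssb / (k - 1)) / msw), k - 1, int(N - k)


def two_sample_t_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled-variance two-sample t from summaries; df = n_a + n_b - 2."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    if se == 0:
        return 0.0, df
    return float((a.mean - b.mean) / se), df


def chisq_2x2(tab: Crosstab2x2) -> tuple[float, int]:
    """Pearson chi-square, no continuity correction, df = 1.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); requires all margins > 0.
    """
    r1, r2, c1, c2 = tab.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    N = r1 + r2
    chi2 = N * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), 1
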