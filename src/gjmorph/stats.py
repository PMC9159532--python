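"""Two-group comparison protocol and box-plot summaries.

Groups are first gated for normality: a sample counts as normal when it
passes either the Shapiro-Wilk test or a Kolmogorov-Smirnov test against
a normal with sample mean and s.d. (Lilliefors-corrected, because the
parameters are estimated; a flag restores the naive KS for auditing).
Two normal groups are compared with the classical pooled-variance
Student's t-test (Welch available behind a flag); otherwise a two-sided
Mann-Whitney U is used, by full enumeration of rank assignments when both
groups have at most 8 observations and by the tie-corrected normal
approximation with continuity correction above that.  Significance is
declared at alpha = 0.05.  No multiple-testing correction is applied;
reports carry the number of comparisons performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "NormalityResult",
    "GroupComparison",
    "BoxSummary",
    "normality_gate",
    "mann_whitney_exact",
    "compare_groups",
    "summarize_box",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    shapiro_p: float
    ks_p: float
    degenerate: bool = False


@dataclass
class GroupComparison:
    """Outcome of one two-group comparison."""

    metric: str
    labels: tuple[str, str]
    n: tuple[int, int]
    shapiro_p: tuple[float, float]
    ks_p: tuple[float, float]
    normal: tuple[bool, bool]
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    exact: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_1": self.labels[0],
            "group_2": self.labels[1],
            "n_1": self.n[0],
            "n_2": self.n[1],
            "shapiro_p_1": self.shapiro_p[0],
            "shapiro_p_2": self.shapiro_p[1],
            "ks_p_1": self.ks_p[0],
            "ks_p_2": self.ks_p[1],
            "normal_1": self.normal[0],
            "normal_2": self.normal[1],
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "exact": self.exact,
        }


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary for a min-to-max box-and-whisker plot."""

    min: float
    q1: float
    median: float
    q3: float
    max: float


def normality_gate(
    values, alpha: float = ALPHA, lilliefors_correction: bool = True
) -> NormalityResult:
    """Normality gate: Shapiro-Wilk OR Kolmogorov-Smirnov must pass.

    The KS test is against a normal with the sample's mean and s.d.; with
    ``lilliefors_correction`` (default) the p-value accounts for the
    estimated parameters.  Zero-variance samples are flagged degenerate
    and fail the gate.  Requires n >= 3.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"normality gate requires n >= 3, got n = {len(x)}")
    if np.ptp(x) == 0:
        return NormalityResult(normal=False, shapiro_p=np.nan, ks_p=np.nan,
                               degenerate=True)
    shapiro_p = float(sps.shapiro(x).pvalue)
    if lilliefors_correction:
        _, ks_p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, ks_p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    ks_p = float(ks_p)
    return NormalityResult(
        normal=(shapiro_p > alpha) or (ks_p > alpha),
        shapiro_p=shapiro_p,
        ks_p=ks_p,
    )


def _u_statistic_from_ranks(rank_sum_a: float, n1: int) -> float:
    return rank_sum_a - n1 * (n1 + 1) / 2.0


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks to
    group one (ties handled through the mid-ranks) and returns
    ``(U1, p)`` with ``p = min(1, 2 * min(P(U <= u), P(U >= u)))``.
    Intended for small groups (n1, n2 <= 8).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistic_from_ranks(ranks[:n1].sum(), n1)
    total = comb(n1 + n2, n1)
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = _u_statistic_from_ranks(ranks[list(idx)].sum(), n1)
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return float(u_obs), float(p)


def _mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float, bool]:
    n1, n2 = len(a), len(b)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        u, p = mann_whitney_exact(a, b)
        return u, p, True
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue), False


def compare_groups(
    a,
    b,
    metric: str = "value",
    labels: tuple[str, str] = ("group_1", "group_2"),
    alpha: float = ALPHA,
    welch: bool = False,
    lilliefors_correction: bool = True,
    exact_max_n: int = 8,
) -> GroupComparison:
    """Gate-then-test comparison of two samples.

    Both groups normal -> two-sided Student's t (pooled variance unless
    ``welch``); otherwise two-sided Mann-Whitney U (exact for small
    groups).  Requires n >= 3 per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"each group needs n >= 3 (got {len(a)} and {len(b)})"
        )
    ga = normality_gate(a, alpha=alpha, lilliefors_correction=lilliefors_correction)
    gb = normality_gate(b, alpha=alpha, lilliefors_correction=lilliefors_correction)
    exact = False
    if ga.normal and gb.normal:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        test_used = "student_t"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        statistic, p, exact = _mann_whitney(a, b, exact_max_n=exact_max_n)
        test_used = "mann_whitney"
    return GroupComparison(
        metric=metric,
        labels=tuple(labels),
        n=(len(a), len(b)),
        shapiro_p=(ga.shapiro_p, gb.shapiro_p),
        ks_p=(ga.ks_p, gb.ks_p),
        normal=(ga.normal, gb.normal),
        test_used=test_used,
        statistic=statistic,
        p_value=p,
        significant=p < alpha,
        exact=exact,
    )


def plot_boxes(
    groups: dict[str, "np.ndarray"], metric: str, path,
) -> None:
    """Write a min-to-max box-and-whisker figure for one metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.2))
    labels = list(groups)
    ax.boxplot([np.asarray(groups[k], float) for k in labels],
               tick_labels=labels, whis=(0, 100))
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_box(values) -> BoxSummary:
    """Five-number summary (min, Q1, median, Q3, max).

    Quartiles use the linear-interpolation convention
    (``numpy.percentile`` default).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("summarize_box requires at least one value")
    mn, q1, med, q3, mx = np.percentile(x, [0, 25, 50, 75, 100])
    return BoxSummary(min=float(mn), q1=float(q1), median=float(med),
                      q3=float(q3), max=float(mx))
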