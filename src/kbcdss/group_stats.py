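"""The study's statistical battery, implemented from first principles over
scipy distribution tails so every printed test statistic can be recomputed
from printed counts and summary statistics.

Covers: Pearson chi-square on contingency tables (no continuity correction),
McNemar-Bowker symmetry test for paired pre/post categories, one-way ANOVA
reconstructed from per-group (n, mean, SD) summaries, one-covariate ANCOVA
(Type III partial F for the group factor), Scheffe all-pairs post hoc
comparisons, noncentral-F power / sample-size calculation, and dropout
inflation of a sample-size estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float

    def formatted_p(self) -> str:
        """Report p to 3 decimals with '< .001' below that, as in the tables."""
        if self.p_value < 0.001:
            return "< .001"
        return f"{self.p_value:.3f}".lstrip("0") or ".000"


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    return t


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    statistic = sum (O - E)^2 / E with E from the row/column margins;
    df = (r-1)(c-1); p from the upper chi-square tail.
    """
    t = _as_table(table)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected <= 0).any():
        raise ValueError("chi-square undefined: zero expected cell")
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def mcnemar_bowker(table) -> TestResult:
    """McNemar-Bowker symmetry test for a square pre x post paired table.

    For 2x2 this is McNemar's (b-c)^2/(b+c) without continuity correction;
    for k x k it is Bowker's sum over i<j of (n_ij - n_ji)^2 / (n_ij + n_ji),
    df = k(k-1)/2, with zero discordant pairs contributing 0 and dropping a
    degree of freedom.  Raises if every off-diagonal pair is zero.
    """
    t = _as_table(table)
    if t.shape[0] != t.shape[1]:
        raise ValueError("paired-category table must be square")
    k = t.shape[0]
    statistic = 0.0
    df = 0
    any_discordant = False
    for i in range(k):
        for j in range(i + 1, k):
            d = t[i, j] + t[j, i]
            if d > 0:
                statistic += (t[i, j] - t[j, i]) ** 2 / d
                df += 1
                any_discordant = True
    if not any_discordant:
        raise ValueError("McNemar-Bowker undefined: all discordant pairs are zero")
    return TestResult(float(statistic), df, float(stats.chi2.sf(statistic, df)))


def anova_from_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """One-way ANOVA F reconstructed from per-group (n, mean, SD) summaries.

    SSB = sum n_i (m_i - grand mean)^2, SSW = sum (n_i - 1) sd_i^2;
    equivalent to the raw-data ANOVA by the moment identity.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    big_n, k = ns.sum(), len(groups)
    grand = float((ns * means).sum() / big_n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df = (k - 1, big_n - k)
    if ssw == 0:
        if ssb == 0:
            return TestResult(0.0, df, 1.0)
        return TestResult(math.inf, df, 0.0)
    f = (ssb / (k - 1)) / (ssw / (big_n - k))
    return TestResult(float(f), df, float(stats.f.sf(f, *df)))


def ancova_one_covariate(group, covariate, outcome) -> TestResult:
    """Group-effect F from the linear model outcome ~ covariate + group.

    Type III (partial) sum of squares for the group factor given the
    covariate, computed by comparing the full least-squares fit against the
    covariate-only reduced fit; df = (k-1, N-k-1).
    """
    group = np.asarray(group)
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(group) == len(x) == len(y)):
        raise ValueError("group, covariate, and outcome must have equal length")
    levels = sorted(set(group.tolist()))
    k = len(levels)
    if k < 2:
        raise ValueError("ANCOVA requires at least 2 groups")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")
    n = len(y)

    # sum-to-zero group coding; last level is the reference
    dummies = np.zeros((n, k - 1))
    for j, lev in enumerate(levels[:-1]):
        dummies[:, j] = (group == lev).astype(float)
        dummies[group == levels[-1], j] = -1.0

    full = np.column_stack([np.ones(n), x, dummies])
    reduced = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("collinear covariate/group encoding")

    sse_full = float(np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2))
    sse_red = float(np.sum((y - reduced @ np.linalg.lstsq(reduced, y, rcond=None)[0]) ** 2))
    df1, df2 = k - 1, n - k - 1
    if df2 < 1:
        raise ValueError("too few observations for ANCOVA")
    f = ((sse_red - sse_full) / df1) / (sse_full / df2)
    return TestResult(float(f), (df1, df2), float(stats.f.sf(f, df1, df2)))


@dataclass(frozen=True)
class PairwiseComparison:
    i: int
    j: int
    label_i: str
    label_j: str
    mean_diff: float
    statistic: float  # Scheffe F-ratio (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j))
    critical: float  # (k-1) F_crit(alpha; k-1, N-k)
    significant: bool


@dataclass
class ScheffeResult:
    comparisons: list[PairwiseComparison] = field(default_factory=list)

    def ordering(self) -> str:
        """Render the ordering string the way published tables do: a full
        chain like 'a < c < b' when every adjacent pair (means ascending) is
        significant, otherwise the list of significant pairs ('a < b; a < c')."""
        sig = set()
        ordered = self._ordered_labels()
        for c in self.comparisons:
            if c.significant:
                lo, hi = (c.label_i, c.label_j) if c.mean_diff < 0 else (c.label_j, c.label_i)
                sig.add((lo, hi))
        chain = all(
            (ordered[idx], ordered[idx + 1]) in sig for idx in range(len(ordered) - 1)
        )
        if chain and len(ordered) > 1:
            return " < ".join(ordered)
        return "; ".join(f"{lo} < {hi}" for lo, hi in sorted(sig))

    def _ordered_labels(self) -> list[str]:
        # mean_diff = m_i - m_j lets us reconstruct relative means and order labels
        if not self.comparisons:
            return []
        rel = {self.comparisons[0].label_i: 0.0}
        changed = True
        while changed:
            changed = False
            for c in self.comparisons:
                if c.label_i in rel and c.label_j not in rel:
                    rel[c.label_j] = rel[c.label_i] - c.mean_diff
                    changed = True
                elif c.label_j in rel and c.label_i not in rel:
                    rel[c.label_i] = rel[c.label_j] + c.mean_diff
                    changed = True
        return [lab for lab, _ in sorted(rel.items(), key=lambda kv: kv[1])]


def scheffe_posthoc(
    groups: Sequence[GroupSummary], msw: float, alpha: float = 0.05
) -> ScheffeResult:
    """Scheffe all-pairs post hoc comparisons after a significant ANOVA.

    Pair (i, j) is significant iff
    (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j)) > (k-1) F_crit(alpha; k-1, N-k).
    """
    if msw <= 0:
        raise ValueError("MSW must be positive")
    k = len(groups)
    if k < 2:
        raise ValueError("post hoc comparison requires at least 2 groups")
    big_n = sum(g.n for g in groups)
    f_crit = float(stats.f.isf(alpha, k - 1, big_n - k))
    critical = (k - 1) * f_crit
    result = ScheffeResult()
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            statistic = diff**2 / (msw * (1 / gi.n + 1 / gj.n))
            result.comparisons.append(
                PairwiseComparison(
                    i=i,
                    j=j,
                    label_i=gi.label or f"g{i}",
                    label_j=gj.label or f"g{j}",
                    mean_diff=diff,
                    statistic=float(statistic),
                    critical=critical,
                    significant=bool(statistic > critical),
                )
            )
    return result


def msw_from_summary(groups: Sequence[GroupSummary]) -> float:
    """Within-group mean square (the ANOVA error term) from summaries."""
    big_n = sum(g.n for g in groups)
    k = len(groups)
    return sum((g.n - 1) * g.sd**2 for g in groups) / (big_n - k)


def ancova_power(
    effect_size_f: float, n_total: int, alpha: float, n_groups: int, n_covariates: int
) -> float:
    """Power of the ANCOVA group F-test under the noncentral-F alternative.

    Convention: noncentrality lambda = f^2 * N_total, df = (k-1, N-k-c).
    """
    df1 = n_groups - 1
    df2 = n_total - n_groups - n_covariates
    if df2 < 1:
        return 0.0
    lam = effect_size_f**2 * n_total
    f_crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


@dataclass(frozen=True)
class SampleSizeResult:
    n_total: int
    n_per_group: int
    achieved_power: float


def ancova_sample_size(
    effect_size_f: float,
    alpha: float,
    power: float,
    n_groups: int,
    n_covariates: int = 1,
    max_n: int = 1_000_000,
) -> SampleSizeResult:
    """Smallest total N whose ANCOVA group-test power reaches the target.

    Monotone in N, so a bisection over [minimal admissible N, upper bound]
    suffices; per-group size is ceil(N / k).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if effect_size_f <= 0:
        raise ValueError("effect size must be positive")
    lo = n_groups + n_covariates + 2  # minimal N with positive error df
    hi = lo
    while ancova_power(effect_size_f, hi, alpha, n_groups, n_covariates) < power:
        hi *= 2
        if hi > max_n:
            raise RuntimeError(f"target power unreachable below N = {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if ancova_power(effect_size_f, mid, alpha, n_groups, n_covariates) >= power:
            hi = mid
        else:
            lo = mid + 1
    return SampleSizeResult(
        n_total=lo,
        n_per_group=math.ceil(lo / n_groups),
        achieved_power=ancova_power(effect_size_f, lo, alpha, n_groups, n_covariates),
    )


def inflate_for_dropout(
    n_per_group: int, dropout_rate: float, n_groups: int
) -> tuple[int, int]:
    """Inflate a per-group sample size for anticipated dropout.

    Returns (per-group n, total n) with per-group = ceil(n / (1 - rate))."""
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    per_group = math.ceil(n_per_group / (1 - dropout_rate))
    return per_group, per_group * n_groups
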