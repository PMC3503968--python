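"""Statistical tests and interval procedures for band-count comparisons.

All procedures are implemented here from their defining formulas, using
scipy only for reference distributions (chi-square, hypergeometric, F,
studentized range).  Every test returns a uniform :class:`TestResult`.

The "one-sided chi-square" reported by legacy statistics packages is the
continuity-corrected (Yates) chi-square with the two-sided tail halved
when the observed direction matches the alternative — that convention is
implemented explicitly here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "AnovaTable",
    "TukeyComparison",
    "yates_chisq_2x2",
    "chisq_ratio_gof",
    "fisher_exact_one_sided",
    "newcombe_wilson_ci",
    "holm_adjust",
    "oneway_anova_tukey",
    "mantel_test",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_one_sided: float
    p_two_sided: float
    df: float | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        for p in (self.p_one_sided, self.p_two_sided):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    return t


def yates_chisq_2x2(table, one_sided_direction: str | None = None) -> TestResult:
    """Continuity-corrected chi-square test of association in a 2x2 table.

    Per-cell correction is max(0, |obs - exp| - 0.5).  The one-sided p is
    half the chi-square(1) upper tail when the observed direction matches
    ``one_sided_direction`` ('greater'/'less', referring to the top-left
    cell relative to its expectation); with the default ``None`` the
    observed direction is taken as the alternative.
    """
    t = _as_2x2(table)
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / n
    corr = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    statistic = float((corr ** 2 / expected).sum())
    p_two = float(stats.chi2.sf(statistic, df=1))
    observed_dir = "greater" if t[0, 0] >= expected[0, 0] else "less"
    if one_sided_direction is None or one_sided_direction == observed_dir:
        p_one = p_two / 2
    else:
        p_one = 1 - p_two / 2
    return TestResult(statistic=statistic, p_one_sided=p_one,
                      p_two_sided=p_two, df=1, direction=observed_dir)


def chisq_ratio_gof(counts: tuple[int, int], ratio: tuple[float, float] = (1, 1),
                    ) -> TestResult:
    """Yates-corrected goodness of fit of two counts to an expected ratio."""
    k1, k2 = counts
    if k1 < 0 or k2 < 0 or k1 + k2 == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    n = k1 + k2
    r1, r2 = ratio
    e1, e2 = n * r1 / (r1 + r2), n * r2 / (r1 + r2)
    statistic = 0.0
    for o, e in ((k1, e1), (k2, e2)):
        corr = max(abs(o - e) - 0.5, 0.0)
        statistic += corr ** 2 / e
    p_two = float(stats.chi2.sf(statistic, df=1))
    direction = "greater" if k1 >= e1 else "less"
    return TestResult(statistic=float(statistic), p_one_sided=p_two / 2,
                      p_two_sided=p_two, df=1, direction=direction)


def fisher_exact_one_sided(table) -> TestResult:
    """Fisher's exact test via the hypergeometric tail in the observed direction.

    The two-sided p sums all tables with point probability not exceeding
    the observed one (the standard small-p definition).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    a = t[0, 0]
    n = int(t.sum())
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    hg = stats.hypergeom(n, row1, col1)
    mean_a = row1 * col1 / n if n else 0.0
    if a >= mean_a:
        p_one = float(hg.sf(a - 1))
        direction = "greater"
    else:
        p_one = float(hg.cdf(a))
        direction = "less"
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hg.pmf(support)
    p_two = float(pmf[pmf <= hg.pmf(a) * (1 + 1e-9)].sum())
    return TestResult(statistic=float(a), p_one_sided=min(p_one, 1.0),
                      p_two_sided=min(p_two, 1.0), df=None, direction=direction)


def newcombe_wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a single binomial proportion.

    The method recommended for proportions reported with confidence
    intervals in comparative band-count work; closed form from inverting
    the score test.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid successes/trials ({k}, {n})")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    z2 = z * z
    denom = 1 + z2 / n
    centre = (p + z2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    lower = 0.0 if k == 0 else max(0.0, centre - half)
    upper = 1.0 if k == n else min(1.0, centre + half)
    return (lower, upper)


def holm_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down (sequential Bonferroni) multiple-testing correction.

    Returns (reject flags, adjusted p-values) in the input order.  The
    step-down rule rejects the i-th smallest p while p_(i) <= alpha/(m-i+1);
    adjusted p-values are the running maximum of (m-i+1) p_(i), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject, adjusted


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f: float
    p: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass(frozen=True)
class TukeyComparison:
    group_i: int
    group_j: int
    mean_diff: float
    q_statistic: float
    p: float


def oneway_anova_tukey(groups) -> tuple[AnovaTable, list[TukeyComparison]]:
    """Fixed-effects one-way ANOVA with Tukey HSD pairwise comparisons.

    Tukey p-values use the studentized-range distribution at the
    within-group degrees of freedom, with the Tukey–Kramer harmonic-mean
    adjustment for unequal group sizes.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(gs)
    all_v = np.concatenate(gs)
    grand = all_v.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, all_v.size - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    table = AnovaTable(ss_between=float(ss_between), ss_within=float(ss_within),
                       df_between=df_b, df_within=df_w, f=float(f), p=p)
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se = math.sqrt(ms_w / 2 * (1 / gs[i].size + 1 / gs[j].size)) if ms_w else 0.0
            q = abs(diff) / se if se else (0.0 if diff == 0 else math.inf)
            pq = float(stats.studentized_range.sf(q, k, df_w)) if se else (
                1.0 if diff == 0 else 0.0)
            comparisons.append(TukeyComparison(group_i=i, group_j=j,
                                               mean_diff=float(diff),
                                               q_statistic=float(q), p=pq))
    return table, comparisons


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel_test(d1, d2, n_perm: int = 9999, seed: int | None = None) -> TestResult:
    """Mantel correlation between two distance matrices with permutation p.

    Pearson correlation of lower-triangle entries; the null distribution
    permutes rows/columns of the second matrix simultaneously, with the
    identity permutation included in the reference set, so the one-sided
    p is at least 1/(n_perm + 1).  When n! <= n_perm all permutations are
    enumerated instead, giving the exact permutation p.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and matched")
    for d in (a, b):
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    n = a.shape[0]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _lower_triangle(a)

    def corr(perm: np.ndarray) -> float:
        y = _lower_triangle(b[np.ix_(perm, perm)])
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(np.arange(n))
    if math.factorial(n) <= n_perm:
        ref = np.array([corr(np.array(p)) for p in permutations(range(n))])
        p_one = float((ref >= observed - 1e-12).mean())
        p_two = float((np.abs(ref) >= abs(observed) - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        ge = ge_abs = 1  # identity permutation included
        for _ in range(n_perm):
            r = corr(rng.permutation(n))
            if r >= observed - 1e-12:
                ge += 1
            if abs(r) >= abs(observed) - 1e-12:
                ge_abs += 1
        p_one = ge / (n_perm + 1)
        p_two = ge_abs / (n_perm + 1)
    return TestResult(statistic=observed, p_one_sided=min(p_one, 1.0),
                      p_two_sided=min(p_two, 1.0), df=None,
                      direction="greater" if observed >= 0 else "less")
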