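"""The statistical battery used across the study's comparisons.

Paired S/N comparisons use the two-sided Wilcoxon signed-rank test; group
comparisons use Kruskal-Wallis with Sidak-adjusted pairwise follow-ups or
one-way ANOVA with Tukey's HSD; threshold dispersions use the two-sample
Ansari-Bradley test; suppressed-fraction contrasts use the 2x2 chi-square.

The Ansari-Bradley test is implemented here directly: pooled midranks are
scored ``min(rank, N+1-rank)``, the statistic is the score sum of the first
sample, and the two-sided p-value comes from exact enumeration of all
subset assignments for pooled N <= 20 (a permutation null, valid under
ties) or from a tie-robust normal approximation above.  The other tests
delegate to scipy behind this module's result type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError

#: largest sample size (after zero removal) for the exact signed-rank null
WILCOXON_EXACT_MAX_N = 25
#: largest pooled size for exact Ansari-Bradley enumeration
ANSARI_EXACT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    tails: str = "two_sided"
    groups: tuple | None = None   # labels of the compared groups, if pairwise

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the null distribution is exact for up to
    25 nonzero differences without ties in |d|, and a normal approximation
    otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ParameterError("paired samples must have equal length >= 2")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks_tied = np.unique(np.abs(d)).size < d.size
    exact = d.size <= WILCOXON_EXACT_MAX_N and not ranks_tied
    res = sps.wilcoxon(d, method="exact" if exact else "approx",
                       correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="wilcoxon_signed_rank" + ("_exact" if exact else ""),
                      n=(int(d.size),))


def _ansari_scores(pooled: np.ndarray) -> np.ndarray:
    r = sps.rankdata(pooled)               # midranks under ties
    N = pooled.size
    return np.minimum(r, N + 1 - r)


def ansari_bradley(sample_x, sample_y) -> TestResult:
    """Two-sample Ansari-Bradley test for a difference in dispersion."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("both samples need n >= 2")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        raise DegenerateInputError("all pooled values identical; dispersion "
                                   "test undefined")
    scores = _ansari_scores(pooled)
    n, m = x.size, y.size
    N = n + m
    ab = float(scores[:n].sum())

    if N <= ANSARI_EXACT_MAX_N:
        # permutation null: enumerate every assignment of n scores to x
        total = comb(N, n)
        le = ge = 0
        for subset in combinations(range(N), n):
            t = scores[list(subset)].sum()
            if t <= ab + 1e-9:
                le += 1
            if t >= ab - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        method = "ansari_bradley_exact"
    else:
        mean = n * scores.sum() / N
        var = (n * m * (N * np.sum(scores ** 2) - scores.sum() ** 2)
               / (N ** 2 * (N - 1)))
        if var <= 0:
            raise DegenerateInputError("zero variance in Ansari-Bradley scores")
        z = (ab - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "ansari_bradley_normal"
    return TestResult(statistic=ab, p_value=float(min(p, 1.0)), method=method,
                      n=(int(n), int(m)))


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (df = 1), without Yates
    continuity correction unless requested."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ParameterError("table must be a 2x2 nonnegative count table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError("zero row or column margin")
    res = sps.chi2_contingency(t, correction=correction)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="chi_square_2x2" + ("_yates" if correction else ""),
                      n=(int(t.sum()),))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment p' = 1 - (1 - p)^m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def omnibus_posthoc(groups, family: str = "kruskal_sidak",
                    labels=None) -> list[TestResult]:
    """Omnibus test plus all pairwise post-hoc comparisons.

    ``kruskal_sidak``: Kruskal-Wallis omnibus, then pairwise two-sided
    Mann-Whitney U tests with Sidak adjustment over the number of pairs.
    ``anova_tukey``: one-way ANOVA omnibus, then Tukey's HSD (already
    family-adjusted).  The omnibus result comes first in the returned list.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ParameterError("need >= 2 groups with n >= 2 each")
    labels = list(labels) if labels is not None else list(range(len(groups)))
    sizes = tuple(int(g.size) for g in groups)
    pairs = list(combinations(range(len(groups)), 2))
    out: list[TestResult] = []

    if family == "kruskal_sidak":
        H, p = sps.kruskal(*groups)
        out.append(TestResult(float(H), float(p), "kruskal_wallis", sizes))
        for i, j in pairs:
            U, praw = sps.mannwhitneyu(groups[i], groups[j],
                                       alternative="two-sided")
            out.append(TestResult(float(U), sidak_adjust(float(praw), len(pairs)),
                                  "mannwhitney_sidak", (sizes[i], sizes[j]),
                                  groups=(labels[i], labels[j])))
    elif family == "anova_tukey":
        if any(np.ptp(g) == 0 for g in groups):
            raise DegenerateInputError("a group has zero variance; ANOVA undefined")
        F, p = sps.f_oneway(*groups)
        out.append(TestResult(float(F), float(p), "one_way_anova", sizes))
        hsd = sps.tukey_hsd(*groups)
        for i, j in pairs:
            out.append(TestResult(float(hsd.statistic[i, j]),
                                  float(hsd.pvalue[i, j]), "tukey_hsd",
                                  (sizes[i], sizes[j]),
                                  groups=(labels[i], labels[j])))
    else:
        raise ParameterError(f"unknown family {family!r}")
    return out


def results_table(results: list[TestResult]):
    """Tidy table of test results (method, statistic, p, sizes, groups)."""
    import pandas as pd

    return pd.DataFrame([{
        "method": r.method, "statistic": r.statistic, "p_value": r.p_value,
        "n": "x".join(str(k) for k in r.n), "tails": r.tails,
        "groups": "" if r.groups is None else f"{r.groups[0]}|{r.groups[1]}",
    } for r in results])
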