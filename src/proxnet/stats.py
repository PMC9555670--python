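"""Supporting statistical tests, implemented from first principles.

Three classical procedures back the descriptive comparisons around the
network model: the Mann-Whitney U test for contact durations (exact
permutation null for small samples, tie-corrected normal approximation with
continuity correction for large ones), Welch's unequal-variance two-sample t
test for shopping-experience ratings, and simple linear regression with an F
test for the crowdedness/contacts relation.  Only distribution functions
(normal, t, F) are taken from scipy; the statistics and null distributions
themselves are computed here.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

#: above this many (x, y) pairings the exact permutation null is replaced by
#: the tie-corrected normal approximation
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class LinregResult:
    slope: float
    intercept: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    n: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i < y_j} + 0.5 * #ties, computed by sorting."""
    # counts via searchsorted: for each y, how many x are strictly below / tied
    xs = np.sort(x)
    below = np.searchsorted(xs, y, side="left").sum()
    tied = (np.searchsorted(xs, y, side="right") - np.searchsorted(xs, y, side="left")).sum()
    return float(below) + 0.5 * float(tied)


def _exact_u_distribution(values: np.ndarray, n1: int) -> np.ndarray:
    """Permutation-null counts of 2U over all C(n1+n2, n1) splits.

    Dynamic programme over tie groups of the pooled sample: state = number of
    values assigned to the first sample so far, tracking twice the U
    statistic (integer even with ties).  Returns an array ``counts`` with
    ``counts[u2]`` = number of splits with 2U = u2.
    """
    n = len(values)
    n2 = n - n1
    _, group_sizes = np.unique(values, return_counts=True)
    max_u2 = 2 * n1 * n2
    dp = np.zeros((n1 + 1, max_u2 + 1))
    dp[0, 0] = 1.0
    done = 0  # values processed so far
    for g in group_sizes:
        new = np.zeros_like(dp)
        for gx in range(0, int(g) + 1):
            gy = int(g) - gx
            w = comb(int(g), gx)
            for cx in range(0, min(done, n1) + 1):
                if cx + gx > n1 or done - cx + gy > n2:
                    continue
                row = dp[cx]
                if not row.any():
                    continue
                # y's in this group see cx earlier (smaller) x's in full,
                # plus half-credit for the gx*gy within-group ties
                shift = 2 * gy * cx + gx * gy
                new[cx + gx, shift:] += w * row[: max_u2 + 1 - shift]
        dp = new
        done += int(g)
    return dp[n1]


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``U`` counts pairs with ``x_i < y_j`` plus half a point per tie.  In
    ``exact`` mode the two-sided p-value enumerates the permutation null of U
    over all splits of the pooled sample (ties handled exactly);  in
    ``normal`` mode it uses the normal approximation with tie-corrected
    variance and continuity correction.  ``auto`` picks exact when
    ``n1 * n2 <= 10_000``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if n1 * n2 <= EXACT_LIMIT else "normal"
    if mode == "exact":
        counts = _exact_u_distribution(np.concatenate([x, y]), n1)
        center = n1 * n2  # = 2 * (n1*n2/2)
        dev = abs(round(2 * u) - center)
        u2 = np.arange(len(counts))
        p = float(counts[np.abs(u2 - center) >= dev].sum() / comb(n1 + n2, n1))
        method = "mann-whitney-exact"
    elif mode == "normal":
        pooled = np.concatenate([x, y])
        _, t = np.unique(pooled, return_counts=True)
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - float(((t**3 - t).sum())) / (n * (n - 1)))
        if var <= 0:  # all observations tied
            return TestResult(u, 1.0, "mann-whitney-normal", n1, n2)
        diff = u - mean_u
        cc = min(0.5, abs(diff))  # continuity correction toward the mean
        z = (abs(diff) - cc) / np.sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        method = "mann-whitney-normal"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=u, p_value=p, method=method, n1=n1, n2=n2)


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t test with Satterthwaite degrees of freedom.

    ``t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2)``.  With zero
    variance in both samples and equal means the statistic is 0 and p = 1;
    zero pooled variance with unequal means gives an infinite statistic,
    reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    num = x.mean() - y.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if num == 0:
            return TestResult(0.0, 1.0, "welch-t", n1, n2, df=float(n1 + n2 - 2))
        return TestResult(float(np.sign(num) * np.inf), 0.0, "welch-t", n1, n2,
                          df=float(n1 + n2 - 2))
    t = num / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(1.0, p), method="welch-t",
                      n1=n1, n2=n2, df=float(df))


def simple_linreg(x, y) -> LinregResult:
    """Ordinary least squares of y on x with the overall F test.

    ``F = (R^2 / (1 - R^2)) * (n - 2)`` on (1, n-2) degrees of freedom;
    ``R^2 = 1 - SSE/SST``.  A constant predictor raises
    :class:`ValueError`; a constant response gives slope 0, R^2 = 0, F = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("predictor is constant")
    sst = float(((y - y.mean()) ** 2).sum())
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    if sst == 0:
        return LinregResult(0.0, intercept, 0.0, 1, n - 2, 1.0, 0.0, n)
    sse = float(((y - intercept - slope * x) ** 2).sum())
    r2 = 1.0 - sse / sst
    if r2 >= 1.0:  # perfect fit
        return LinregResult(slope, intercept, float("inf"), 1, n - 2, 0.0, 1.0, n)
    f = (r2 / (1.0 - r2)) * (n - 2)
    p = float(sps.f.sf(f, 1, n - 2))
    return LinregResult(slope, intercept, float(f), 1, n - 2, p, float(r2), n)
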