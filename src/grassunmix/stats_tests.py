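"""Paired nonparametric change tests for per-bin abundance counts.

The change question — did the distribution of fractional cover shift between
two acquisition years? — is answered on paired per-bin pixel tallies: the ten
histogram bins of a cover class in year 1 paired with the same bins in year 2.
Paired differences are screened for normality (Shapiro-Wilk, Q-Q points) and
compared with the exact Wilcoxon signed-rank test, the robust alternative to
a paired t-test when differences are non-normal.

The exact Wilcoxon null distribution is built by convolution over the integer
ranks: with n non-zero differences and no ties among their absolute values,
the signed-rank statistic V under H0 is the sum of a uniformly random subset
of {1..n}, so the distribution of V is the coefficient sequence of
prod_i (1 + z^i) over 2^n. This is exact in integer arithmetic.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .errors import DataError, NumericalError
from .types import HistogramSummary, TestResult

__all__ = [
    "paired_bin_differences",
    "signed_rank_null_distribution",
    "wilcoxon_signed_rank_exact",
    "shapiro_wilk",
    "qq_points",
]


def paired_bin_differences(
    hist_a: HistogramSummary, hist_b: HistogramSummary
) -> np.ndarray:
    """Elementwise bin-count differences ``counts(a) - counts(b)``.

    Both histograms must share an identical bin structure; order is
    preserved so the i-th difference belongs to the i-th abundance bin.
    """
    if hist_a.counts.size != hist_b.counts.size or not np.allclose(
        hist_a.bin_edges, hist_b.bin_edges
    ):
        raise DataError("histograms have mismatched bin structure")
    return hist_a.counts.astype(np.int64) - hist_b.counts.astype(np.int64)


def signed_rank_null_distribution(n: int) -> np.ndarray:
    """Exact null counts of the signed-rank statistic V for sample size n.

    Returns an integer array c of length n(n+1)/2 + 1 where c[v] is the
    number of the 2^n sign assignments with rank-sum v. Built by the
    polynomial convolution prod_{i=1}^{n} (1 + z^i).
    """
    if n < 0:
        raise DataError("n must be non-negative")
    max_v = n * (n + 1) // 2
    counts = np.zeros(max_v + 1, dtype=object)
    counts[0] = 1
    for i in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[i:] = counts[:-i] if i else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(x, y) -> TestResult:
    """Wilcoxon signed-rank test of paired samples, exact where possible.

    Differences ``d = x - y``; zero differences are dropped (Wilcoxon's
    original treatment), absolute values are ranked with average ranks for
    ties, and V is the sum of ranks of positive differences. When the
    absolute differences are tie-free and the effective sample size is at
    most 25, the two-sided p-value is exact:
    ``p = min(1, 2 * min(P(V <= v), P(V >= v)))`` over the full 2^n sign
    distribution. Otherwise a normal approximation with continuity and tie
    corrections is used and flagged in ``method``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    if x.size < 1:
        raise DataError("need at least one pair")
    d = x - y
    nonzero = d != 0
    d = d[nonzero]
    n = d.size
    notes = []
    if n == 0:
        raise DataError("all paired differences are zero; V is undefined")
    if n < x.size:
        notes.append(f"dropped {x.size - n} zero difference(s)")

    ranks = scipy.stats.rankdata(np.abs(d), method="average")
    v = float(ranks[d > 0].sum())

    has_ties = np.unique(np.abs(d)).size < n
    if not has_ties and n <= 25:
        null = signed_rank_null_distribution(n)
        total = 1 << n  # 2^n
        vi = int(round(v))  # integer when tie-free
        p_le = int(null[: vi + 1].sum()) / total
        p_ge = int(null[vi:].sum()) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        if has_ties:
            notes.append("ties among |d|; normal approximation")
        else:
            notes.append("n > 25; normal approximation")
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise NumericalError("degenerate variance in normal approximation")
        sd = np.sqrt(var)
        # continuity correction toward the mean
        if v > mean:
            z = (v - mean - 0.5) / sd
        elif v < mean:
            z = (v - mean + 0.5) / sd
        else:
            z = 0.0
        p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
        method = "approximate"

    return TestResult(
        statistic_name="V",
        statistic=v,
        p_two_sided=float(p),
        n_effective=int(n),
        method=method,
        notes="; ".join(notes),
    )


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston AS R94 approximation).

    Valid for 3 <= n <= 5000. W close to 1 is consistent with normality;
    the p-value comes from Royston's transformed-normal approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise DataError("sample must be 1-D")
    n = x.size
    if not 3 <= n <= 5000:
        raise DataError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if np.ptp(x) == 0:
        raise NumericalError("zero-variance sample; W is undefined")
    w, p = scipy.stats.shapiro(x)
    return TestResult(
        statistic_name="W",
        statistic=float(w),
        p_two_sided=float(p),
        n_effective=int(n),
        method="approximate",
        notes="Royston (1995) AS R94",
    )


def qq_points(x) -> np.ndarray:
    """Normal Q-Q plot coordinates for a sample.

    Uses Blom-type plotting positions ``(i - 0.375) / (n + 0.25)`` mapped
    through the standard normal inverse CDF, paired with the sorted sample.
    Returns an (n, 2) array of (theoretical quantile, ordered value).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise DataError("Q-Q points require at least 2 observations")
    i = np.arange(1, n + 1)
    positions = (i - 0.375) / (n + 0.25)
    theoretical = scipy.stats.norm.ppf(positions)
    return np.column_stack([theoretical, np.sort(x)])
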