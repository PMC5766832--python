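"""Self-contained nonparametric statistics used across the pipeline.

Implements the small set of tests the analyses rely on: the inverse
standard-normal CDF (for d'), the Wilcoxon signed-rank test (paired
condition comparisons), the Mann-Whitney two-sample rank test
(between-group comparisons), the Bonferroni-Holm step-down adjustment,
and a Dunn-type joint-ranking multiple-comparison procedure for
comparing more than two groups (used for evoked-response latency and
peak-time orderings across cortical areas).

Exact null distributions are enumerated by dynamic programming where
small samples make the normal approximation unreliable; beyond those
sizes the standard tie-corrected normal approximations are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "inverse_normal_cdf",
    "normal_cdf",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "holm_adjust",
    "dunn_holland_wolfe",
    "PairwiseResult",
]


# ---------------------------------------------------------------------------
# Inverse normal CDF
# ---------------------------------------------------------------------------

# Coefficients of Acklam's rational approximation to the inverse
# standard-normal CDF (|relative error| < 1.15e-9 before refinement).
_A = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
      1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
_B = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
      6.680131188771972e+01, -1.328068155288572e+01)
_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
      -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
      3.754408661907416e+00)

_P_LOW = 0.02425


def normal_cdf(z: float) -> float:
    """Standard normal cumulative distribution function."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def _acklam(p: float) -> float:
    if p < _P_LOW:
        q = math.sqrt(-2.0 * math.log(p))
        return ((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5])
                / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0))
    if p > 1.0 - _P_LOW:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5])
                 / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0))
    q = p - 0.5
    r = q * q
    return ((((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4]) * r + _A[5]) * q
            / (((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4]) * r + 1.0))


def inverse_normal_cdf(p):
    """Quantile function Z(p) of the standard normal distribution.

    Rational approximation refined by one Halley step, giving
    |CDF(Z(p)) - p| well below 1e-9 over the open unit interval.
    Accepts a scalar or array; raises ``ValueError`` outside (0, 1).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")

    def _one(pi: float) -> float:
        z = _acklam(pi)
        # Halley refinement using the exact CDF/PDF.
        e = normal_cdf(z) - pi
        u = e * math.sqrt(2.0 * math.pi) * math.exp(z * z / 2.0)
        return z - u / (1.0 + z * u / 2.0)

    if arr.ndim == 0:
        return _one(float(arr))
    return np.vectorize(_one)(arr)


# ---------------------------------------------------------------------------
# Rank utilities
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by midranks."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(x: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

_EXACT_WILCOXON_N = 25


def _signed_rank_null_sf(n: int, w: float) -> float:
    """P(W+ >= w) under the exact signed-rank null (no ties).

    Dynamic programming over the generating polynomial
    prod_{r=1..n} (1 + x^r) / 2^n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()
    k = int(math.ceil(w - 1e-12))
    return float(counts[k:].sum() / total)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float] | None = None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    With one argument, `a` is treated as the paired differences.  Zero
    differences are dropped (standard convention); if all differences
    are zero the test is vacuous and p = 1 is returned.  The null is
    enumerated exactly for n <= 25 when the absolute differences are
    untied; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    else:
        d = a
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    if n < 2:
        raise ValueError("need at least 2 nonzero paired differences")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= _EXACT_WILCOXON_N and not has_ties:
        w_hi = max(w_pos, n * (n + 1) / 2.0 - w_pos)
        p = 2.0 * _signed_rank_null_sf(n, w_hi)
        return min(1.0, p)

    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var_w <= 0:
        return 1.0
    z = (w_pos - mean_w - 0.5 * np.sign(w_pos - mean_w)) / math.sqrt(var_w)
    return min(1.0, 2.0 * (1.0 - normal_cdf(abs(z))))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_EXACT_MW_MIN_N = 8


def _mw_null_sf(n1: int, n2: int, u: float) -> float:
    """P(U >= u) under the exact Mann-Whitney null (no ties)."""
    # counts[k][u] = number of arrangements; iterate the standard recurrence
    # via the Gaussian binomial generating function.
    max_u = n1 * n2
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # product_{i=1..n1} (1 - x^(n2+i)) / (1 - x^i)
    for i in range(1, n1 + 1):
        # multiply by 1/(1-x^i): prefix-sum with stride i
        for j in range(i, max_u + 1):
            counts[j] += counts[j - i]
        # multiply by (1 - x^(n2+i))
        k = n2 + i
        if k <= max_u:
            for j in range(max_u, k - 1, -1):
                counts[j] -= counts[j - k]
    total = counts.sum()
    k = int(math.ceil(u - 1e-12))
    return float(counts[k:].sum() / total)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney (rank-sum) p-value.

    Exact enumeration of the U null for min(n) <= 8 on tie-free data;
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    has_ties = len(np.unique(pooled)) < n1 + n2
    if min(n1, n2) <= _EXACT_MW_MIN_N and not has_ties:
        u_hi = max(u1, n1 * n2 - u1)
        return min(1.0, 2.0 * _mw_null_sf(n1, n2, u_hi))

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    var_u = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var_u <= 0:
        return 1.0
    z = (u1 - mean_u - 0.5 * np.sign(u1 - mean_u)) / math.sqrt(var_u)
    return min(1.0, 2.0 * (1.0 - normal_cdf(abs(z))))


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values.

    Sort ascending, multiply the k-th smallest by (m - k + 1), enforce
    monotone non-decrease along the sorted order, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Dunn-Holland-Wolfe joint-rank multiple comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    """All-pairs rank comparison outcome.

    Attributes
    ----------
    labels : group labels in input order.
    mean_rank_diff : matrix of R̄_i − R̄_j over the joint ranking.
    critical : per-pair critical difference at family level alpha.
    significant : boolean matrix, symmetric with a False diagonal.
    alpha : family-wise level used.
    """

    labels: list
    mean_rank_diff: np.ndarray
    critical: np.ndarray
    significant: np.ndarray
    alpha: float

    def pair(self, i, j) -> bool:
        a, b = self.labels.index(i), self.labels.index(j)
        return bool(self.significant[a, b])


def dunn_holland_wolfe(groups: Sequence[Sequence[float]],
                       labels: Sequence | None = None,
                       alpha: float = 0.05) -> PairwiseResult:
    """All-pairs comparison of k groups by joint ranking of pooled data.

    Observations from all groups are ranked together (midranks for
    ties); each pair (i, j) is declared different when the absolute
    difference of mean ranks exceeds the large-sample critical value

        z_{1 - alpha / (k (k - 1))} * sqrt(S * (1/n_i + 1/n_j)),

    where S = N(N+1)/12 − Σ(t³−t)/(12(N−1)) is the tie-corrected rank
    variance factor, which controls the family-wise error at ``alpha``.
    Degenerate all-equal data yields no significant pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([len(g) for g in groups])
    if np.any(sizes < 1):
        raise ValueError("every group must be non-empty")
    if labels is None:
        labels = list(range(k))
    labels = list(labels)

    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks = np.empty(k)
    start = 0
    for i, n in enumerate(sizes):
        mean_ranks[i] = ranks[start:start + n].mean()
        start += n

    s_factor = (n_total * (n_total + 1) / 12.0
                - _tie_term(pooled) / (12.0 * (n_total - 1)))
    s_factor = max(s_factor, 0.0)
    n_pairs = k * (k - 1) // 2
    diff = mean_ranks[:, None] - mean_ranks[None, :]
    se = np.sqrt(s_factor * (1.0 / sizes[:, None] + 1.0 / sizes[None, :]))
    if s_factor > 0:
        z_crit = inverse_normal_cdf(1.0 - alpha / (2.0 * n_pairs))
        critical = z_crit * se
    else:
        critical = np.full_like(se, math.inf)
    significant = np.abs(diff) > critical
    np.fill_diagonal(significant, False)
    return PairwiseResult(labels=labels, mean_rank_diff=diff,
                          critical=critical, significant=significant,
                          alpha=alpha)
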