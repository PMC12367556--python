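"""Shared statistical primitives.

Exact two-sided binomial (sign) tests computed entirely in log space,
Benjamini–Hochberg FDR adjustment, and a Spearman correlation with
average-rank tie handling.  These are the building blocks used by the
flux/gene sign-test summaries, the size–expression correlations and the
multiple-comparison reporting throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "BinomialTestResult",
    "exact_binomial_two_sided",
    "bh_adjust",
    "spearman_rho",
    "rank_test",
]

# Relative tolerance when comparing point masses to the observed mass; keeps
# outcomes with mathematically equal likelihood (e.g. the mirror outcome at
# p0 = 0.5) inside the rejection set despite floating-point rounding.
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class BinomialTestResult:
    """Result of an exact two-sided binomial test.

    Attributes
    ----------
    k, n : int
        Observed successes and number of trials.
    p0 : float
        Null success probability.
    p_two_sided : float
        Minimum-likelihood two-sided p-value, in (0, 1].
    log10_p : float
        log10 of the p-value, finite down to ~-300 and beyond (computed in
        log space, so it never underflows to -inf for nonzero p).
    """

    k: int
    n: int
    p0: float
    p_two_sided: float
    log10_p: float


def _log_pmf(j: np.ndarray, n: int, p0: float) -> np.ndarray:
    """Log binomial point masses via log-factorials (no underflow)."""
    j = np.asarray(j, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p0)
        + (n - j) * np.log1p(-p0)
    )


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    """Exact two-sided binomial test with the minimum-likelihood rule.

    The p-value sums the null probability of every outcome whose point mass
    does not exceed the observed one (up to a relative tie tolerance):

        p = sum_{j : P(j) <= P(k) (1 + eps)} P(j)

    All point masses are computed via log-factorials and accumulated with
    log-sum-exp, so p-values far below the double-precision underflow
    threshold of intermediate terms are still returned accurately and
    ``log10_p`` stays finite down to at least -300.

    Parameters
    ----------
    k, n : int
        Successes out of trials, 0 <= k <= n.
    p0 : float
        Null success probability, in (0, 1).  The sign tests in this
        pipeline all use 0.5.
    """
    if not (float(k).is_integer() and float(n).is_integer()):
        raise ValueError("k and n must be integers")
    k, n = int(k), int(n)
    if n < 0 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")

    j = np.arange(n + 1)
    logp = _log_pmf(j, n, p0)
    log_obs = logp[k]
    # minimum-likelihood rejection set, with relative tie tolerance in log space
    keep = logp <= log_obs + np.log1p(_TIE_EPS)
    log_p_total = logsumexp(logp[keep])
    log_p_total = min(log_p_total, 0.0)  # cap at 1
    p = float(np.exp(log_p_total))
    return BinomialTestResult(
        k=k, n=n, p0=p0, p_two_sided=min(p, 1.0) if p > 0 else p,
        log10_p=float(log_p_total / np.log(10.0)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Order-preserving: output[i] corresponds to input[i].  Monotonicity is
    enforced by the cumulative minimum over the sorted sequence; results are
    clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the average ranks.  The two-sided
    p-value uses the t approximation for n >= 10 and exact enumeration of
    all rank permutations for n < 10 (feasible since 9! = 362,880).

    Returns ``(nan, nan)`` is never silently produced: constant input raises
    ``ValueError`` so an undefined correlation cannot masquerade as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation is undefined")

    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n < 10:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t approximation, two-sided
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value for small n (enumerate all orderings of y)."""
    from itertools import permutations

    n = rx.size
    sx = rx - rx.mean()
    denom_x = np.sqrt((sx**2).sum())
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        sy = ryp - ryp.mean()
        r = float((sx * sy).sum() / (denom_x * np.sqrt((sy**2).sum())))
        if abs(r) >= abs(rho_obs) - tol:
            count += 1
        total += 1
    return count / total


def rank_test(a, b, paired: bool = False) -> float:
    """Two-sided rank test p-value between two samples.

    Wilcoxon signed-rank for paired data, Mann–Whitney/Wilcoxon rank-sum
    otherwise.  Exact null distribution is used for small samples (n < 25),
    the normal approximation above that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return 1.0
        mode = "exact" if a.size < 25 else "approx"
        return float(sps.wilcoxon(a, b, mode=mode).pvalue)
    method = "exact" if (a.size < 25 and b.size < 25) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
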