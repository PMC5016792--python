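"""Shared statistical primitives.

Hypergeometric (one-sided Fisher) enrichment, Benjamini-Hochberg FDR,
add-one empirical permutation p-values, Pearson correlation, and the
Poisson likelihood-ratio test used for spectral-count differential
abundance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "hypergeometric_enrichment",
    "bh_fdr",
    "empirical_p",
    "pearson_r2",
    "poisson_lr_stat",
    "poisson_lr_table",
]


class DomainError(ValueError):
    """A statistical precondition was violated."""


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided over-representation test on a 2x2 table.

    k of n query genes fall in a category of size K drawn from a
    background universe of size N.  ``fold`` is (k/n)/(K/N); ``p`` is the
    hypergeometric upper tail P(X >= k), which equals the one-sided
    Fisher's exact p-value.  ``q`` is filled in by callers that adjust a
    family of tests; NaN until then.
    """

    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    q: float = field(default=float("nan"))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n_pairs: int


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """One-sided (over-representation) hypergeometric enrichment.

    p = sum_{i=k..min(n,K)} C(K,i) C(N-K,n-i) / C(N,n), evaluated in log
    space via the survival function for numerical stability.

    Raises :class:`DomainError` naming the violated inequality.
    """
    for name, ok in [
        ("0 <= k", k >= 0),
        ("k <= n", k <= n),
        ("k <= K", k <= K),
        ("n <= N", n <= N),
        ("K <= N", K <= N),
        ("n >= 1", n >= 1),
        ("N >= 1", N >= 1),
    ]:
        if not ok:
            raise DomainError(f"enrichment bound violated: {name} "
                              f"(k={k}, n={n}, K={K}, N={N})")
    # sf(k-1) = P(X >= k); includes the whole tail so k = 0 gives exactly 1.
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else float("nan")
    return EnrichmentResult(k=k, n=n, K=K, N=N, fold=fold, p=min(p, 1.0))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; values are clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def empirical_p(observed: float, null_values: Sequence[float],
                direction: str = "greater") -> float:
    """Add-one empirical p-value against a permutation/resampling null.

    p = (1 + #{null >= observed}) / (M + 1) for direction "greater"
    (<= for "less").  Ties count against the observed value, and the
    add-one rule means the result is never 0: the minimum attainable
    value is 1/(M+1).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise DomainError("null_values must be non-empty")
    if direction == "greater":
        hits = int(np.sum(null >= observed))
    elif direction == "less":
        hits = int(np.sum(null <= observed))
    else:
        raise DomainError(f"unknown direction {direction!r}")
    return (1 + hits) / (null.size + 1)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation r and r² between paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise DomainError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("constant vector: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, r_squared=r * r, n_pairs=int(x.size))


def _pois_ll(total_count: float, total_size: float) -> float:
    # Profile Poisson log-likelihood up to terms that cancel in the LR:
    # sum_i [c_i log(lam s_i) - lam s_i]; with lam = C/S this is
    # C log(C/S) - C plus count-only terms that are identical under both
    # hypotheses and therefore omitted.
    if total_count == 0:
        return 0.0
    return total_count * np.log(total_count / total_size) - total_count


def poisson_lr_stat(counts_a: Sequence[int], sizes_a: Sequence[float],
                    counts_b: Sequence[int], sizes_b: Sequence[float],
                    ) -> tuple[float, float]:
    """Likelihood-ratio test for equal Poisson rates across two groups.

    Counts in group g are modelled as Poisson(lambda_g * size_i) with the
    batch exposures `sizes`.  The MLEs are closed form
    (lambda_hat = sum counts / sum sizes), so
    LR = 2 [l(lam_a, lam_b) - l(lam_0)], and p comes from the chi-square
    survival function with 1 degree of freedom.  LR = 0 when the two
    rate estimates coincide.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    sa = np.asarray(sizes_a, dtype=float)
    sb = np.asarray(sizes_b, dtype=float)
    if ca.size == 0 or cb.size == 0:
        raise DomainError("each group needs at least one batch")
    if np.any(ca < 0) or np.any(cb < 0):
        raise DomainError("counts must be non-negative")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise DomainError("sizes must be strictly positive")
    Ca, Sa = float(ca.sum()), float(sa.sum())
    Cb, Sb = float(cb.sum()), float(sb.sum())
    ll_alt = _pois_ll(Ca, Sa) + _pois_ll(Cb, Sb)
    ll_null = _pois_ll(Ca + Cb, Sa + Sb)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    return lr, float(sps.chi2.sf(lr, df=1))


def poisson_lr_table(counts_a: np.ndarray, sizes_a: np.ndarray,
                     counts_b: np.ndarray, sizes_b: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`poisson_lr_stat` over rows (one test per protein).

    ``counts_*`` are (n_proteins, n_batches) arrays, ``sizes_*`` the
    per-batch exposure vectors shared by all rows.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    sa = float(np.sum(sizes_a))
    sb = float(np.sum(sizes_b))
    if sa <= 0 or sb <= 0:
        raise DomainError("sizes must sum to a positive total")
    Ca = ca.sum(axis=1)
    Cb = cb.sum(axis=1)
    Ct = Ca + Cb

    def xlogx_over(c, s):
        out = np.zeros_like(c)
        nz = c > 0
        out[nz] = c[nz] * np.log(c[nz] / s) - c[nz]
        return out

    lr = 2.0 * (xlogx_over(Ca, sa) + xlogx_over(Cb, sb) - xlogx_over(Ct, sa + sb))
    lr = np.maximum(lr, 0.0)
    return lr, sps.chi2.sf(lr, df=1)
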