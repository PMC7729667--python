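"""Hypergeometric enrichment of drought-responsive genes for TFBS presence.

For each TF family the universe is partitioned by DEG status and TFBS
status; the upper-tail hypergeometric probability P(X >= k) tests whether
DEGs are over-represented among TFBS-carrying genes.  Family-wise error is
controlled by Bonferroni: with alpha = 0.05 over 11 families the per-test
critical value is 0.05/11 ~= 4.55e-3, and significance uses the strict
inequality p < critical.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    tf_family: str
    N: int  # universe size
    K: int  # DEGs in the universe
    n: int  # TFBS-carrying genes in the universe
    k: int  # DEGs carrying a TFBS
    p_value: float  # upper tail, P(X >= k)
    p_deplete: float  # lower tail, P(X <= k), reported descriptively
    direction: str  # "enriched" | "depleted"
    alpha: float = 0.05
    m: int | None = None
    critical: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValueError("inconsistent contingency counts")
        if self.k < max(0, self.K + self.n - self.N):
            raise ValueError("k below the hypergeometric support")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    _check_bounds(N, K, n, k)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X <= k), the depletion tail."""
    _check_bounds(N, K, n, k)
    return float(hypergeom.cdf(k, N, K, n))


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside hypergeometric support "
            f"[{max(0, K + n - N)}, {min(K, n)}] for N={N}, K={K}, n={n}"
        )


def test_family(
    tf_family: str,
    universe_ids: set[str] | list[str],
    deg_ids: set[str] | list[str],
    tfbs_gene_ids: set[str] | list[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Build the 2x2 contingency for one TF family and test enrichment.

    ``universe_ids`` is the family's gene universe (its propagated target
    set, or a shared global universe); ``deg_ids`` must be a subset of it;
    ``tfbs_gene_ids`` is intersected with the universe.  Depletion is
    reported via the lower tail but never enters the significance decision.
    """
    universe = set(universe_ids)
    degs = set(deg_ids)
    offenders = degs - universe
    if offenders:
        raise ValueError(
            f"DEG ids outside the universe for {tf_family!r}: "
            f"{sorted(offenders)[:5]}"
        )
    tfbs = set(tfbs_gene_ids) & universe
    N, K, n = len(universe), len(degs), len(tfbs)
    k = len(degs & tfbs)
    p_up = hypergeom_upper_tail(N, K, n, k)
    p_down = hypergeom_lower_tail(N, K, n, k)
    expected = K * n / N if N else 0.0
    return EnrichmentResult(
        tf_family=tf_family,
        N=N,
        K=K,
        n=n,
        k=k,
        p_value=p_up,
        p_deplete=p_down,
        direction="enriched" if k >= expected else "depleted",
        alpha=alpha,
    )


def bonferroni(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Attach the per-test critical value alpha/m and the strict decision."""
    if not results:
        raise ValueError("bonferroni needs at least one result")
    m = len(results)
    critical = alpha / m
    for r in results:
        r.alpha = alpha
        r.m = m
        r.critical = critical
        r.significant = r.p_value < critical
    return results
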