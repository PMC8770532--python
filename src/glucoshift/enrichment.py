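"""Pathway enrichment and pathway-consistency statistics.

Two exact binomial statistics drive the functional interpretation:

* **Enrichment**: for a pathway with K members in a transcriptome of N
  genes, the number k of members falling inside a subset of n genes is
  tested against Binomial(n, K/N); the upper tail P(X >= k) measures
  over-representation, and log2(k·N / (K·n)) is the fold enrichment.

* **Consistency**: for a pathway in which M of N enzymes are regulated
  in the same direction, each enzyme is treated as a trial with success
  probability 2^-M, and the upper tail P(X >= M) of Binomial(N, 2^-M)
  measures non-random co-regulation.

Both use an exact term summation (big-integer binomial coefficients,
no normal or Poisson approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from statsmodels.stats.multitest import multipletests

from .types import PathwayMap, ValidationError


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    Terms are summed as exact binomial coefficients times float powers,
    which keeps relative error at a few ulps per term; a log-space
    fallback handles the deep-underflow regime.
    """
    if not (0 <= k <= n):
        raise ValidationError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"success probability must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    q = 1.0 - p
    total = 0.0
    # sum ascending j from k; once terms decay, stop when negligible
    prev = math.inf
    for j in range(k, n + 1):
        term = math.comb(n, j) * (p ** j) * (q ** (n - j))
        total += term
        if term < prev and term < total * 1e-18:
            break
        prev = term
    if total > 0.0:
        return min(total, 1.0)
    # all terms underflowed: recompute the dominant stretch in log space
    logs = []
    for j in range(k, n + 1):
        lt = (
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * math.log(p)
            + (n - j) * math.log(q)
        )
        logs.append(lt)
        if len(logs) > 1 and lt < logs[0] - 50:
            break
    m = max(logs)
    return math.exp(m) * sum(math.exp(v - m) for v in logs)


def binomial_lower_strict_tail(k: int, n: int, p: float) -> float:
    """P(X < k) = 1 - P(X >= k), computed by direct summation for testing."""
    if k == 0:
        return 0.0
    q = 1.0 - p
    return min(sum(math.comb(n, j) * p**j * q ** (n - j) for j in range(0, k)), 1.0)


@dataclass
class EnrichmentResult:
    """One Table-1-style row: pathway counts and the binomial tail p-value."""

    pathway_id: str
    name: str
    K: int  # pathway genes in the transcriptome
    k: int  # pathway genes in the subset
    n: int  # subset size
    N: int  # transcriptome size
    fc_log2: float  # log2(k*N / (K*n)); NaN when k == 0
    p_value: float
    q_value: float = float("nan")  # BH across pathways, reported but not thresholded


@dataclass
class ConsistencyResult:
    """Direction-consistency call for one pathway."""

    pathway_name: str
    n_enzymes: int
    m_same: int
    direction: str  # "up" | "down" | "none"
    p_success: float  # 2^-M
    p_value: float


def pathway_enrichment(
    subset: Iterable[str],
    pmap: PathwayMap,
    transcriptome_size: int,
    gene_universe: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Binomial over-representation of each pathway within a gene subset.

    ``transcriptome_size`` is N (the annotated transcriptome); when a
    ``gene_universe`` is supplied, subset members must belong to it.
    Results are sorted by p-value ascending; pathways with no overlap
    get p = 1 and an undefined (NaN) fold enrichment.
    """
    subset = set(subset)
    n = len(subset)
    N = int(transcriptome_size)
    if N < n:
        raise ValidationError(f"transcriptome size N={N} smaller than subset n={n}")
    if gene_universe is not None:
        universe = set(gene_universe)
        stray = subset - universe
        if stray:
            raise ValidationError(
                f"subset members absent from transcriptome universe: {sorted(stray)[:5]}"
            )
    results = []
    for pid, (name, members) in pmap.items():
        K = len(members)
        k = len(members & subset)
        if K == 0 or k == 0:
            fc = float("nan")
            p = 1.0
        else:
            fc = math.log2(k * N / (K * n))
            p = binomial_upper_tail(k, n, K / N)
        results.append(EnrichmentResult(pid, name, K, k, n, N, fc, p))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def pathway_consistency(n_enzymes: int, m_same: int, direction: str = "up") -> ConsistencyResult:
    """The 2^-M co-regulation test: P(X >= M) for X ~ Binomial(N, 2^-M).

    With M of N enzymes changed in one direction, the chance of any one
    enzyme matching that direction by coin-flip is modelled as 2^-M.
    """
    if not (0 <= m_same <= n_enzymes):
        raise ValidationError(
            f"require 0 <= M <= N, got M={m_same}, N={n_enzymes}"
        )
    if m_same == 0:
        return ConsistencyResult("", n_enzymes, 0, "none", 1.0, 1.0)
    p_success = 2.0 ** (-m_same)
    p = binomial_upper_tail(m_same, n_enzymes, p_success)
    return ConsistencyResult("", n_enzymes, m_same, direction, p_success, p)
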