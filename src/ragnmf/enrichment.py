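"""Hypergeometric overlap tests between candidate driver lists and benchmarks.

The over-representation question: drawing ``n`` candidate genes from a
universe of ``N`` genes of which ``K`` belong to a benchmark set, how
surprising is an overlap of at least ``x``? The upper-tail hypergeometric
probability P(X >= x) answers it; smaller p means stronger enrichment.
The universe is the set of genes present in the (filtered) mutation
matrix — benchmark genes absent from it cannot overlap any candidate list
and are dropped before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .io import GeneSetCollection


@dataclass
class OverlapResult:
    """Outcome of one candidate-list vs benchmark-set overlap test."""

    set_name: str
    universe_size: int
    set_size: int
    candidates_size: int
    overlap: int
    p_value: float
    overlap_genes: list[str]


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    Computed in log-space (log-gamma binomial coefficients combined with
    logsumexp) so deep tails do not underflow:

        P(X >= x) = sum_{j=x}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n)
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("x", x)):
        if val != int(val) or val < 0:
            raise ConfigurationError(f"{name} must be a nonnegative integer, got {val!r}")
    N, K, n, x = int(N), int(K), int(n), int(x)
    if K > N or n > N:
        raise ConfigurationError(f"infeasible counts: K={K}, n={n} must not exceed N={N}")
    if x > min(K, n):
        raise ConfigurationError(f"overlap x={x} exceeds min(K, n)={min(K, n)}")
    if x == 0:
        return 1.0
    j_lo = max(x, n - (N - K))  # below this C(N-K, n-j) vanishes
    j_hi = min(K, n)
    if j_lo > j_hi:
        return 1.0
    j = np.arange(j_lo, j_hi + 1)
    log_terms = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def test_overlap(candidates, benchmark, universe, set_name: str = "") -> OverlapResult:
    """Hypergeometric overlap of a candidate gene list with one benchmark set.

    ``candidates`` must lie within ``universe``; ``benchmark`` is first
    intersected with the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigurationError("universe is empty")
    cand = set(candidates)
    stray = cand - universe_set
    if stray:
        raise ConfigurationError(
            f"{len(stray)} candidate gene(s) outside the universe, e.g. {sorted(stray)[:3]}"
        )
    bench = set(benchmark) & universe_set
    shared = sorted(cand & bench)
    p = hypergeom_upper_tail(len(universe_set), len(bench), len(cand), len(shared))
    return OverlapResult(
        set_name=set_name,
        universe_size=len(universe_set),
        set_size=len(bench),
        candidates_size=len(cand),
        overlap=len(shared),
        p_value=p,
        overlap_genes=shared,
    )


def benchmark_report(candidates, collection: GeneSetCollection, universe):
    """Test a candidate list against every set in a collection.

    Returns ``(table, summary)``: a DataFrame with one row per benchmark
    set (p-values plus a supplementary Benjamini-Hochberg column) and a
    summary dict whose headline statistic is the unadjusted arithmetic
    mean of the per-set p-values, alongside the minimum.
    """
    if len(collection) == 0:
        raise ConfigurationError("gene-set collection is empty")
    results = [
        test_overlap(candidates, members, universe, set_name=name)
        for name, members in collection.sets.items()
    ]
    pvals = np.array([r.p_value for r in results])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "universe_size": [r.universe_size for r in results],
            "set_size": [r.set_size for r in results],
            "candidates_size": [r.candidates_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": pvals,
            "p_value_bh": p_adj,
            "overlap_genes": [",".join(r.overlap_genes) for r in results],
        }
    )
    summary = {
        "n_sets": len(results),
        "mean_p_value": float(pvals.mean()),
        "min_p_value": float(pvals.min()),
    }
    return table, summary


def pairwise_overlap_count(list_a, list_b) -> tuple[int, list[str]]:
    """Number of genes shared by two candidate lists, plus the shared symbols."""
    shared = sorted(set(list_a) & set(list_b))
    return len(shared), shared
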