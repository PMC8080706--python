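"""Independent brute-force oracles shared across test modules."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def simplex_projection_oracle(v, budget):
    """Exhaustive active-set search over all support patterns."""
    v = np.asarray(v, dtype=float)
    best, best_val = None, np.inf
    for r in range(1, v.size + 1):
        for active in itertools.combinations(range(v.size), r):
            w = np.zeros_like(v)
            shift = (v[list(active)].sum() - budget) / r
            w[list(active)] = v[list(active)] - shift
            if (w >= -1e-12).all():
                val = float(np.sum((w - v) ** 2))
                if val < best_val - 1e-15:
                    best, best_val = np.maximum(w, 0), val
    return best


def hypergeom_tail_exact(N, K, n, x):
    """Exact upper-tail hypergeometric probability via big-integer binomials."""
    num = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(x, min(K, n) + 1)
        if n - j <= N - K
    )
    return Fraction(num, comb(N, n))


def objective_oracle(X, state, graph, config):
    """Elementwise double-loop evaluation of the weighted objective."""
    m, p = X.shape
    total = 0.0
    for s in range(m):
        for g in range(p):
            r = X[s, g] - float(state.U[s] @ state.Z[g])
            total += state.M[s] * state.W[g] * r * r
    k = state.Z.shape[1]
    for i in range(p):
        for j in range(p):
            for r_ in range(k):
                total += (
                    config.lambda_graph
                    * state.Z[i, r_]
                    * graph.laplacian[i, j]
                    * state.Z[j, r_]
                )
    total += config.alpha * float(np.sum(state.W**2))
    total += config.beta * float(np.sum(state.M**2))
    return total
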