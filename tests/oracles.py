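"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: the Welch oracle is a
direct textbook-formula transcription evaluated with mpmath arbitrary
precision, the rank-sum oracle enumerates every group assignment, and the
BH oracle is a literal double-loop reading of the step-up definition.
"""

from __future__ import annotations

import itertools
import math

import mpmath
import numpy as np

mpmath.mp.dps = 50


def welch_p_reference(a, b) -> float:
    """Two-sided Welch t-test p-value from the textbook formulas."""
    a = [mpmath.mpf(x) for x in a]
    b = [mpmath.mpf(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / mpmath.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-sided p via the regularized incomplete beta function
    x = df / (df + t**2)
    p = mpmath.betainc(df / 2, mpmath.mpf(1) / 2, 0, x, regularized=True)
    return float(p)


def wilcoxon_p_enumeration(a, b) -> float:
    """Exact two-sided rank-sum p-value by enumerating all assignments.

    Assumes no ties.  p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1,
    under the exact permutation null of the pooled ranks.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    na, n = len(a), len(a) + len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n, "enumeration oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + 1), na):
        us.append(sum(combo) - na * (na + 1) / 2)
    total = len(us)
    le = sum(1 for u in us if u <= u_obs)
    ge = sum(1 for u in us if u >= u_obs)
    return min(1.0, 2.0 * min(le, ge) / total)


def bh_reference(p) -> np.ndarray:
    """Literal step-up definition: adj_(r) = min_{s>=r} p_(s) * m / s."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for r in range(m):
        adj_sorted[r] = min(
            min(sorted_p[s] * m / (s + 1) for s in range(r, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def dirichlet_mean(counts, prior=0.5) -> np.ndarray:
    """Closed-form posterior mean (n_i + prior) / (N + D * prior)."""
    counts = np.asarray(counts, dtype=float)
    return (counts + prior) / (counts.sum() + counts.size * prior)


def dirichlet_coord_sd(counts, prior=0.5) -> np.ndarray:
    """Closed-form per-coordinate standard deviation of the Dirichlet."""
    alpha = np.asarray(counts, dtype=float) + prior
    a0 = alpha.sum()
    var = alpha * (a0 - alpha) / (a0**2 * (a0 + 1))
    return np.sqrt(var)


def min_exact_rank_p(n1: int, n2: int) -> float:
    """Smallest achievable exact two-sided rank-sum p at group sizes n1, n2."""
    return min(1.0, 2.0 / math.comb(n1 + n2, n1))
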