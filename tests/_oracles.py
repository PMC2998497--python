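"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive enumeration and direct
formula evaluation — and shares no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np


def average_ranks(values) -> list[float]:
    """Average ranks computed by direct position counting (no scipy)."""
    values = list(values)
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        # ranks of the tied block are smaller+1 .. smaller+equal; take the mean
        ranks.append(smaller + (equal + 1) / 2)
    return ranks


def pearson(x, y) -> float:
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / sqrt(sxx * syy)


def spearman_rho(x, y) -> float:
    """Rank-then-Pearson Spearman correlation."""
    return pearson(average_ranks(x), average_ranks(y))


def partial_corr_recursion(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Single-control partial correlation recursion formula."""
    return (r_xy - r_xz * r_yz) / sqrt((1 - r_xz**2) * (1 - r_yz**2))


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denominator = comb(n, c1)
    probs = {
        aa: Fraction(comb(r1, aa) * comb(r2, c1 - aa), denominator)
        for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def mann_whitney_exact_enumeration(a, b) -> tuple[float, float]:
    """(U, two-sided p) by enumerating all group-a rank assignments (no ties)."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for group_a_positions in combinations(range(n1 + n2), n1):
        r = sum(pos + 1 for pos in group_a_positions)
        us.append(r - n1 * (n1 + 1) / 2)
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def eigh_oracle(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric matrix, descending, sign-oriented
    so the largest-magnitude entry of each eigenvector is positive."""
    eigvals, eigvecs = np.linalg.eig(corr)
    eigvals = eigvals.real
    eigvecs = eigvecs.real
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    return eigvals, eigvecs
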