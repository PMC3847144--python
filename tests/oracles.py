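"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by enumeration, direct summation or
numerical integration, staying independent of the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


def fisher_two_sided_enum(a: int, b: int, c: int, d: int, rtol: float = 1e-7) -> float:
    """Two-sided Fisher p by full enumeration of same-margin tables.

    Sums hypergeometric probabilities of every table whose probability does
    not exceed the observed one (within relative tolerance).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(pmf[pmf <= p_obs * (1 + rtol)].sum())


def kendall_tau_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b by O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom if denom else float("nan")


def fitch_bruteforce(adjacency: dict, root, leaf_states: dict) -> int:
    """Minimum substitution count by exhaustive internal-node labelling.

    ``adjacency`` maps node -> list of children; leaves appear with empty
    child lists. ``leaf_states`` maps leaf -> state or None (missing). A
    missing leaf is labelled freely, like an internal node. The alphabet is
    the set of observed states (an unobserved state never helps a minimum).
    """
    nodes = list(adjacency)
    observed = sorted({s for s in leaf_states.values() if s is not None})
    if not observed:
        return 0
    free = [
        n
        for n in nodes
        if adjacency[n] or leaf_states.get(n) is None  # internal or missing leaf
    ]
    fixed = {n: leaf_states[n] for n in nodes if not adjacency[n] and leaf_states.get(n) is not None}
    edges = [(p, ch) for p in nodes for ch in adjacency[p]]
    best = math.inf
    for combo in itertools.product(observed, repeat=len(free)):
        lab = dict(zip(free, combo)) | fixed
        cost = sum(lab[p] != lab[ch] for p, ch in edges)
        best = min(best, cost)
    return int(best)


def negbin_marginal_quadrature(x: int, d: float, a: float, b: float) -> float:
    """P1(x; d) by numerical integration of Poisson over a Gamma(a, b) rate."""

    def integrand(lam: float) -> float:
        return stats.poisson.pmf(x, lam * d) * stats.gamma.pdf(lam, a, scale=1.0 / b)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def shared_rate_marginal_quadrature(
    x1: int, x2: int, d1: float, d2: float, a: float, b: float
) -> float:
    """P0(x1, x2) by integrating the product of Poissons over one shared rate."""

    def integrand(lam: float) -> float:
        return (
            stats.poisson.pmf(x1, lam * d1)
            * stats.poisson.pmf(x2, lam * d2)
            * stats.gamma.pdf(lam, a, scale=1.0 / b)
        )

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def rbh_bruteforce(score_ab: np.ndarray, score_ba: np.ndarray) -> set[tuple[int, int]]:
    """Mutual-argmax pairs from two score matrices (NaN = no hit).

    ``score_ab[i, j]`` scores query i of genome A against subject j of
    genome B; ties break toward the lowest subject index (mirroring the
    lexicographic tie-break on ids like b0, b1, ...).
    """
    pairs = set()
    for i in range(score_ab.shape[0]):
        row = score_ab[i]
        if np.all(np.isnan(row)):
            continue
        j = int(np.nanargmax(row))
        rev = score_ba[j]
        if np.all(np.isnan(rev)):
            continue
        if int(np.nanargmax(rev)) == i:
            pairs.add((i, j))
    return pairs
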