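"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles (enumeration, exact
rational arithmetic, closed forms) and deliberately shares no code with
the package under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# set partitions
# ---------------------------------------------------------------------------

def all_partitions(n: int):
    """Every partition of items 0..n-1 as a label tuple (restricted growth)."""

    def rec(i, labels, k):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels.append(c)
            yield from rec(i + 1, labels, max(k, c + 1))
            labels.pop()

    yield from rec(0, [], 0)


# ---------------------------------------------------------------------------
# partition agreement by exhaustive pair counting / direct entropy
# ---------------------------------------------------------------------------

def ari_bruteforce(u, v) -> float:
    """ARI via enumeration of all item pairs."""
    n = len(u)
    together_u = together_v = together_both = 0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        su = u[i] == u[j]
        sv = v[i] == v[j]
        together_u += su
        together_v += sv
        together_both += su and sv
    expected = together_u * together_v / total
    maximum = (together_u + together_v) / 2
    if maximum == expected:
        return 1.0
    return (together_both - expected) / (maximum - expected)


def nmi_bruteforce(u, v, variant: str = "sqrt") -> float:
    """NMI via direct entropy sums over the joint label distribution."""
    n = len(u)
    from collections import Counter

    cu = Counter(u)
    cv = Counter(v)
    cuv = Counter(zip(u, v))
    hu = -sum((c / n) * math.log(c / n) for c in cu.values())
    hv = -sum((c / n) * math.log(c / n) for c in cv.values())
    if hu == 0 and hv == 0:
        return 1.0
    if hu == 0 or hv == 0:
        return 0.0
    mi = sum(
        (c / n) * math.log((c / n) / ((cu[a] / n) * (cv[b] / n)))
        for (a, b), c in cuv.items()
    )
    if variant == "sqrt":
        denom = math.sqrt(hu * hv)
    elif variant == "max":
        denom = max(hu, hv)
    else:
        denom = (hu + hv) / 2
    return min(1.0, max(0.0, mi / denom))


# ---------------------------------------------------------------------------
# exact hypergeometric co-occurrence
# ---------------------------------------------------------------------------

def hypergeom_pmf_exact(N: int, N1: int, N2: int) -> dict[int, Fraction]:
    """P(j) = C(N1, j) C(N-N1, N2-j) / C(N, N2) as exact rationals."""
    denom = math.comb(N, N2)
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    return {
        j: Fraction(math.comb(N1, j) * math.comb(N - N1, N2 - j), denom)
        for j in range(lo, hi + 1)
    }


# ---------------------------------------------------------------------------
# k-NN Jaccard by explicit set enumeration
# ---------------------------------------------------------------------------

def knn_sets_bruteforce(points, k: int) -> list[set]:
    """k nearest neighbor sets, Euclidean, self excluded, index tie-break."""
    n = len(points)
    sets = []
    for i in range(n):
        d = sorted(
            (sum((a - b) ** 2 for a, b in zip(points[i], points[j])), j)
            for j in range(n)
            if j != i
        )
        sets.append({j for _, j in d[:k]})
    return sets


def jaccard_bruteforce(points, k: int) -> dict[tuple[int, int], float]:
    """Nonzero Jaccard weights between cells appearing in each other's kNN."""
    sets = knn_sets_bruteforce(points, k)
    n = len(points)
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            if j in sets[i] or i in sets[j]:
                inter = len(sets[i] & sets[j])
                if inter:
                    out[(i, j)] = inter / len(sets[i] | sets[j])
    return out


# ---------------------------------------------------------------------------
# modularity by definition, maximized by exhaustive partition search
# ---------------------------------------------------------------------------

def modularity(edges, weights, labels, n: int) -> float:
    """Newman modularity of a weighted undirected graph."""
    two_m = 2 * sum(weights)
    strength = [0.0] * n
    for (a, b), w in zip(edges, weights):
        strength[a] += w
        strength[b] += w
    q = 0.0
    for (a, b), w in zip(edges, weights):
        if labels[a] == labels[b]:
            q += 2 * w / two_m
    for a in range(n):
        for b in range(n):
            if labels[a] == labels[b]:
                q -= strength[a] * strength[b] / (two_m * two_m)
    return q


def best_partition_bruteforce(edges, weights, n: int):
    """Maximum-modularity partition by exhaustive search (n <= 10)."""
    best_q, best_p = -math.inf, None
    for p in all_partitions(n):
        q = modularity(edges, weights, p, n)
        if q > best_q + 1e-12:
            best_q, best_p = q, p
    return best_p, best_q


# ---------------------------------------------------------------------------
# nonnegative least squares on a grid (KKT reference)
# ---------------------------------------------------------------------------

def nnls_grid_oracle(A, y, hi: float, steps: int = 201):
    """Brute-force min ||Ax - y|| over a nonnegative grid (2 variables)."""
    import numpy as np

    A = np.asarray(A, float)
    y = np.asarray(y, float)
    grid = np.linspace(0, hi, steps)
    best, best_x = math.inf, None
    for x0 in grid:
        for x1 in grid:
            x = np.array([x0, x1])
            r = A @ x - y
            v = float(r @ r)
            if v < best - 1e-15:
                best, best_x = v, x
    return best_x, best
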