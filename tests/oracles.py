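"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (scalar loops, exhaustive enumeration)
and shares no code with the package's vectorized or library-backed
implementations.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial

import numpy as np


def tom_scalar(a: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loop over the formula."""
    a = np.array(a, dtype=float)
    n = a.shape[0]
    a = a.copy()
    for i in range(n):
        a[i, i] = 0.0
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += a[i, u] * a[u, j]
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return out


def maximal_cliques_exhaustive(nodes: list, edges: set[frozenset]) -> list[set]:
    """All maximal cliques by testing every subset (n <= ~15)."""

    def is_clique(sub):
        return all(frozenset((u, v)) in edges for u, v in combinations(sub, 2))

    nodes = list(nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if is_clique(sub):
                cliques.append(set(sub))
    return [
        c
        for c in cliques
        if not any(c < other for other in cliques)
    ]


def mcc_exhaustive(nodes: list, edges: set[frozenset]) -> dict:
    scores = {v: 0 for v in nodes}
    for clique in maximal_cliques_exhaustive(nodes, edges):
        if len(clique) < 2:
            continue
        for v in clique:
            scores[v] += factorial(len(clique) - 1)
    return scores


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating every same-margin table.

    Table probabilities from factorials directly (no scipy)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        # hypergeometric P(X = x) with the table's margins
        b_, c_, d_ = row1 - x, col1 - x, n - row1 - col1 + x
        if min(x, b_, c_, d_) < 0:
            return 0.0
        return (
            comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def best_subset_intersection(sets: dict[str, set], k: int) -> int:
    """Max intersection size over all k-subsets of datasets (exhaustive)."""
    best = 0
    for sub in combinations(sets, k):
        inter = set.intersection(*(sets[d] for d in sub))
        best = max(best, len(inter))
    return best


def bfs_ball(adj: dict[str, set[str]], seeds: list[str], radius: int) -> set[str]:
    """Union of BFS balls, plain queue implementation."""
    seen = {s: 0 for s in seeds}
    queue = list(seeds)
    while queue:
        v = queue.pop(0)
        if seen[v] == radius:
            continue
        for u in adj.get(v, ()):
            if u not in seen:
                seen[u] = seen[v] + 1
                queue.append(u)
    return set(seen)


def first_pc_eigh(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First right principal axis via eigen-decomposition of the Gram matrix."""
    gram = z.T @ z
    w, v = np.linalg.eigh(gram)
    profile = v[:, -1]
    var = float(w[-1] / w.sum())
    return profile, var


def g4_substring_matches(seq: str, min_run: int, min_loop=1, max_loop=7) -> list[tuple[int, int]]:
    """All (start, end) where a quadruplex pattern match begins at start,
    found by explicit walking, not regex.  Leftmost-greedy non-overlapping."""
    out = []
    i = 0
    n = len(seq)

    def run_len(pos):
        j = pos
        while j < n and seq[j] == "G":
            j += 1
        return j - pos

    while i < n:
        r0 = run_len(i)
        if r0 < min_run:
            i += 1
            continue
        # try to chain three more runs greedily
        end = _chain(seq, i + r0, 3, min_run, min_loop, max_loop)
        if end is not None:
            out.append((i, end))
            i = end
        else:
            i += 1
    return out


def _chain(seq, pos, remaining, min_run, min_loop, max_loop):
    # greedy-longest-loop-first, mirroring regex backtracking order
    if remaining == 0:
        return pos
    n = len(seq)
    for loop in range(max_loop, min_loop - 1, -1):
        j = pos + loop
        if j > n:
            continue
        k = j
        while k < n and seq[k] == "G":
            k += 1
        if k - j >= min_run:
            end = _chain(seq, k, remaining - 1, min_run, min_loop, max_loop)
            if end is not None:
                return end
    return None
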