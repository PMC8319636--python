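"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exact rational arithmetic for the
hypergeometric tail, a literal step-up for Benjamini-Hochberg, and
shortest-path enumeration for betweenness. None of it shares code with
the package.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exact rational summation of the pmf."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def hand_bh(p_values: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up: sort, scale p(i)*m/i, cumulative min."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p_values[i] * m / (pos + 1))
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def _bfs_dist(start: str, adj: dict[str, list[str]]) -> dict[str, int]:
    dist = {start: 0}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def all_shortest_paths(s: str, t: str, adj: dict[str, list[str]]) -> list[tuple[str, ...]]:
    """Every geodesic from s to t, enumerated over the distance-pruned DAG."""
    dist_s = _bfs_dist(s, adj)
    if t not in dist_s:
        return []
    dist_t = _bfs_dist(t, adj)
    d = dist_s[t]
    paths: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        for w in adj[v]:
            # w lies on some geodesic iff its two distances sum to d
            if dist_s.get(w) == dist_s[v] + 1 and dist_s[w] + dist_t.get(w, 10**9) == d:
                extend(path + [w])

    extend([s])
    return paths


def enumeration_betweenness(nodes: list[str], adj: dict[str, list[str]]) -> dict[str, float]:
    """Betweenness by explicit geodesic enumeration, unordered pairs,
    endpoints excluded, unnormalized."""
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(s, t, adj)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc
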