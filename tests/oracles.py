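"""Independent brute-force oracles, kept free of the package's own code paths."""

from itertools import combinations
from math import comb


def hypergeom_pmf_table(N, n, m):
    """Exact hypergeometric pmf over k via integer binomials."""
    denom = comb(N, n)
    return {k: comb(m, k) * comb(N - m, n - k) / denom
            for k in range(max(0, n + m - N), min(n, m) + 1)}


def hypergeom_tail(N, n, m, x, tail):
    pmf = hypergeom_pmf_table(N, n, m)
    if tail == "ge":
        return sum(p for k, p in pmf.items() if k >= x)
    return sum(p for k, p in pmf.items() if k > x)


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up, written directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def pooled_t(a, b):
    """Two-sample pooled-variance t from the textbook formula."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s2 = (sum((v - m1) ** 2 for v in a) + sum((v - m2) ** 2 for v in b)) / (n1 + n2 - 2)
    return (m1 - m2) / ((s2 * (1 / n1 + 1 / n2)) ** 0.5)


def brute_betweenness(nodes, edges):
    """Unnormalized betweenness by explicit all-pairs shortest-path
    enumeration (BFS counting all geodesics)."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        if s == t:
            return []
        paths = [[s]]
        seen_depth = {s: 0}
        depth = 0
        while paths:
            depth += 1
            nxt = []
            found = []
            for p in paths:
                for w in adj[p[-1]]:
                    if w in seen_depth and seen_depth[w] < depth:
                        continue
                    seen_depth[w] = depth
                    q = p + [w]
                    (found if w == t else nxt).append(q)
            if found:
                return found
            paths = nxt
        return []

    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc
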