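"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the definitions with plain
loops over explicit node/edge sets — no networkx, no imports from the
package under test — so agreement with the package is a genuine two-route
check.
"""

from __future__ import annotations

import math


def gibbs_oracle(
    nodes: set[str], edges: set[frozenset[str]], c: dict[str, float]
) -> dict[str, float]:
    """G_i = c_i ln(c_i / S_i), S_i the covered closed-neighborhood sum."""
    scores: dict[str, float] = {}
    for i in nodes:
        if i not in c:
            continue
        if c[i] == 0.0:
            scores[i] = 0.0
            continue
        s = c[i]
        for j in nodes:
            if j != i and frozenset((i, j)) in edges and j in c:
                s += c[j]
        scores[i] = c[i] * math.log(c[i] / s)
    return scores


def select_oracle(
    nodes: set[str], edges: set[frozenset[str]], c: dict[str, float]
) -> tuple[str, str] | None:
    """Exhaustive anchor/partner selection: most negative G, then max-c
    neighbor, lexicographic ties; fall back through ascending-G anchors."""
    scores = gibbs_oracle(nodes, edges, c)
    if not scores:
        return None
    ranked = sorted(scores, key=lambda n: (scores[n], n))
    for anchor in ranked:
        best = None
        for j in sorted(nodes):
            if j != anchor and frozenset((anchor, j)) in edges and j in c:
                if best is None or c[j] > c[best]:
                    best = j
        if best is not None:
            return anchor, best
    return None


def _all_shortest_paths(
    adj: dict[str, set[str]], s: str, t: str
) -> list[list[str]]:
    """Enumerate every shortest s-t path by exhaustive DFS over simple paths."""
    paths: list[list[str]] = []

    def walk(node: str, seen: list[str]) -> None:
        if node == t:
            paths.append(list(seen))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                walk(nxt, seen + [nxt])

    walk(s, [s])
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def betweenness_oracle(
    nodes: set[str], edges: set[frozenset[str]]
) -> dict[str, float]:
    """C_B(V) = sum over unordered pairs {s,t} of sigma(s,t|V)/sigma(s,t)."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    cb = {n: 0.0 for n in nodes}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                cb[v] += through / len(paths)
    return cb


def entropy_oracle(degrees: list[int]) -> float:
    """Shannon entropy (nats) of the degree distribution over degrees >= 1."""
    pos = [d for d in degrees if d >= 1]
    n = len(pos)
    h = 0.0
    for k in set(pos):
        p = pos.count(k) / n
        h -= p * math.log(p)
    return h
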