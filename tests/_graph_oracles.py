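"""Brute-force enumeration oracles for small-graph metrics.

Implemented from first principles (distance matrices by exhaustive relaxation,
shortest-path counting by simple-path enumeration, triangle counting) so they
are independent of the library code under test.  Intended for unweighted
graphs with at most ~7 nodes.
"""

from __future__ import annotations

import itertools
import math


def _distances(nodes, adj):
    """All-pairs shortest-path lengths by Floyd-Warshall (unit edges)."""
    inf = math.inf
    d = {u: {v: (0 if u == v else (1 if v in adj[u] else inf))
             for v in nodes} for u in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def _count_shortest_paths(nodes, adj, s, t, dist):
    """(#shortest s-t paths, {v: #shortest s-t paths through interior v})."""
    if dist[s][t] == math.inf:
        return 0, {}
    total = 0
    through: dict = {}
    frontier = [(s, (s,))]
    while frontier:
        u, path = frontier.pop()
        if u == t:
            if len(path) - 1 == dist[s][t]:
                total += 1
                for v in path[1:-1]:
                    through[v] = through.get(v, 0) + 1
            continue
        if len(path) - 1 >= dist[s][t]:
            continue
        for v in adj[u]:
            if v not in path:
                frontier.append((v, path + (v,)))
    return total, through


def oracle_metrics(nodes, edges):
    """Degree, clustering, betweenness, closeness, density, transitivity,
    number of connected components — by direct enumeration."""
    nodes = list(nodes)
    n = len(nodes)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    m = sum(len(s) for s in adj.values()) // 2

    out: dict = {}
    out["density"] = 0.0 if n < 2 else 2 * m / (n * (n - 1))

    # connected components by flood fill
    seen: set = set()
    comps = 0
    for u in nodes:
        if u in seen:
            continue
        comps += 1
        stack = [u]
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            stack.extend(adj[w] - seen)
    out["n_components"] = comps

    # triangles and clustering
    clustering = {}
    closed_triplets = 0
    open_or_closed = 0
    for u in nodes:
        k = len(adj[u])
        tri = sum(1 for a, b in itertools.combinations(adj[u], 2)
                  if b in adj[a])
        clustering[u] = 0.0 if k < 2 else 2 * tri / (k * (k - 1))
        closed_triplets += tri                # centred at u
        open_or_closed += k * (k - 1) // 2
    out["clustering"] = clustering
    out["transitivity"] = 0.0 if open_or_closed == 0 \
        else closed_triplets / open_or_closed

    dist = _distances(nodes, adj)

    # closeness with the Wasserman-Faust component correction
    closeness = {}
    for u in nodes:
        reach = [v for v in nodes if v != u and dist[u][v] < math.inf]
        if not reach or n < 2:
            closeness[u] = 0.0
            continue
        s = sum(dist[u][v] for v in reach)
        closeness[u] = (len(reach) / s) * (len(reach) / (n - 1))
    out["closeness"] = closeness

    # normalized betweenness by shortest-path enumeration
    betweenness = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        total, through = _count_shortest_paths(nodes, adj, s, t, dist)
        if total == 0:
            continue
        for v, c in through.items():
            betweenness[v] += c / total
    norm = (n - 1) * (n - 2) / 2
    if norm > 0:
        betweenness = {u: b / norm for u, b in betweenness.items()}
    out["betweenness"] = betweenness

    out["degree"] = {u: float(len(adj[u])) for u in nodes}
    return out
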