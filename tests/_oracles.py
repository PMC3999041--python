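"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit loops, BFS,
rank-by-sort) so it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math


def ranks_average(values):
    """Average ranks (1-based) of a sequence, ties averaged, by explicit sort."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


def spearman(x, y):
    """Spearman rho as Pearson on explicit average ranks."""
    return pearson(ranks_average(list(x)), ranks_average(list(y)))


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up q-values by the textbook recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def kruskal_wallis_h(groups):
    """Tie-corrected Kruskal-Wallis H from pooled average ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = ranks_average(pooled)
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = sum(ranks[start : start + k]) / k
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie_sum = sum(c**3 - c for c in counts.values())
    correction = 1.0 - tie_sum / (n**3 - n)
    return h / correction if correction > 0 else float("nan")


def eta_squared(groups):
    pooled = [v for g in groups for v in g]
    grand = sum(pooled) / len(pooled)
    ss_total = sum((v - grand) ** 2 for v in pooled)
    if ss_total == 0:
        return 0.0
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    return ss_between / ss_total


# ---------------------------------------------------------------------------
# graph properties from an edge list, via BFS and explicit loops


def _adjacency(n_nodes, edges):
    adj = [set() for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def graph_properties(n_nodes, edges):
    """Dict of NetworkAnalyzer-style properties for a labeled graph.

    Nodes are 0..n_nodes-1; isolated nodes count. NaN where undefined.
    """
    nan = float("nan")
    if n_nodes == 0:
        return {
            "avg_num_neighbors": nan, "characteristic_path_length": nan,
            "clustering_coefficient": nan, "centralization": nan,
            "density": nan, "heterogeneity": nan,
            "n_nodes": 0, "n_edges": 0, "n_shortest_paths": 0,
        }
    adj = _adjacency(n_nodes, edges)
    degrees = [len(a) for a in adj]
    E = len(edges)
    N = n_nodes

    avg_nn = 2.0 * E / N
    density = 2.0 * E / (N * (N - 1)) if N > 1 else nan

    # BFS all-pairs shortest paths
    total = 0
    n_pairs = 0
    for s in range(N):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t, d in dist.items():
            if t != s:
                total += d
                n_pairs += 1
    cpl = total / n_pairs if n_pairs else nan

    # local clustering over nodes with degree >= 2
    locals_ = []
    for v in range(N):
        k = degrees[v]
        if k < 2:
            continue
        neigh = list(adj[v])
        links = 0
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                if neigh[j] in adj[neigh[i]]:
                    links += 1
        locals_.append(2.0 * links / (k * (k - 1)))
    clustering = sum(locals_) / len(locals_) if locals_ else nan

    if N >= 3:
        centralization = (N / (N - 2.0)) * (max(degrees) / (N - 1.0) - density)
    else:
        centralization = nan

    mean_deg = sum(degrees) / N
    if mean_deg > 0:
        var = sum((d - mean_deg) ** 2 for d in degrees) / N
        heterogeneity = math.sqrt(var) / mean_deg
    else:
        heterogeneity = nan

    return {
        "avg_num_neighbors": avg_nn,
        "characteristic_path_length": cpl,
        "clustering_coefficient": clustering,
        "centralization": centralization,
        "density": density,
        "heterogeneity": heterogeneity,
        "n_nodes": N,
        "n_edges": E,
        "n_shortest_paths": n_pairs,
    }


def all_graphs(n_nodes):
    """Yield every labeled graph on n_nodes as an edge list."""
    pairs = list(itertools.combinations(range(n_nodes), 2))
    for mask in range(1 << len(pairs)):
        yield [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
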