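"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid networkx and the package's own algorithms:
distances come from Floyd-Warshall, path counts from a dynamic program
over distance layers, component membership from union-find, and the
bottleneck score from literal path-walking through explicitly built
shortest-path trees.
"""

from __future__ import annotations

import math
from itertools import combinations

INF = math.inf


def floyd_warshall(nodes: list[str], edges: set[tuple[str, str]]) -> dict:
    dist = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for u, v in edges:
        if u != v:
            dist[(u, v)] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[(i, k)]
            if dik is INF:
                continue
            for j in nodes:
                alt = dik + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def path_counts(nodes: list[str], edges: set[tuple[str, str]], dist: dict) -> dict:
    """sigma[(s, v)] = number of shortest directed paths from s to v."""
    preds: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        if u != v:
            preds[v].append(u)
    sigma = {}
    for s in nodes:
        order = sorted(
            (v for v in nodes if dist[(s, v)] is not INF), key=lambda v: dist[(s, v)]
        )
        for v in order:
            if v == s:
                sigma[(s, v)] = 1
            else:
                sigma[(s, v)] = sum(
                    sigma[(s, u)]
                    for u in preds[v]
                    if dist[(s, u)] is not INF and dist[(s, u)] + 1 == dist[(s, v)]
                )
        for v in nodes:
            sigma.setdefault((s, v), 0)
    return sigma


def brute_force_path_stats(nodes: list[str], edges: set[tuple[str, str]]) -> dict:
    """Diameter, CPL, reachable-pair count and normalized betweenness."""
    nodes = sorted(nodes)
    dist = floyd_warshall(nodes, edges)
    sigma = path_counts(nodes, edges, dist)
    finite = [
        dist[(u, v)] for u in nodes for v in nodes if u != v and dist[(u, v)] is not INF
    ]
    n = len(nodes)
    betweenness = {}
    for v in nodes:
        total = 0.0
        for s in nodes:
            if s == v:
                continue
            for t in nodes:
                if t in (s, v) or dist[(s, t)] is INF:
                    continue
                if dist[(s, v)] is INF or dist[(v, t)] is INF:
                    continue
                if dist[(s, v)] + dist[(v, t)] == dist[(s, t)]:
                    total += sigma[(s, v)] * sigma[(v, t)] / sigma[(s, t)]
        norm = (n - 1) * (n - 2) if n > 2 else 1
        betweenness[v] = total / norm
    return {
        "diameter": max(finite) if finite else 0,
        "cpl": (sum(finite) / len(finite)) if finite else float("nan"),
        "reachable_pairs": len(finite),
        "betweenness": betweenness,
    }


def union_find_components(nodes: list[str], edges: set[tuple[str, str]]) -> list[set]:
    parent = {v: v for v in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[str, set] = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


def brute_force_bottleneck(nodes: list[str], edges: set[tuple[str, str]]) -> dict:
    """BN(v) by literally walking tree paths root->target for every root.

    The shortest-path tree uses the same parent rule as the package (the
    lexicographically smallest equal-distance predecessor), but the
    "paths meeting at v" count is obtained by walking every root->target
    parent chain and tallying the nodes it crosses, rather than via
    subtree sizes.
    """
    nodes = sorted(nodes)
    dist = floyd_warshall(nodes, edges)
    simple_edges = {(u, v) for u, v in edges if u != v}
    bn = {v: 0 for v in nodes}
    for root in nodes:
        tree_nodes = [v for v in nodes if dist[(root, v)] is not INF]
        parent = {}
        for v in tree_nodes:
            if v == root:
                continue
            cands = [
                u
                for u in tree_nodes
                if (u, v) in simple_edges and dist[(root, u)] + 1 == dist[(root, v)]
            ]
            parent[v] = min(cands)
        meets = {v: 0 for v in tree_nodes}
        for target in tree_nodes:
            if target == root:
                continue
            node = target
            while node != root:
                meets[node] += 1  # the path root->target crosses `node`
                node = parent[node]
        quarter = len(tree_nodes) / 4
        for v in tree_nodes:
            if v != root and meets[v] > quarter:
                bn[v] += 1
    return bn


def random_digraph(rng, n_max: int = 30, n_min: int = 3):
    """A random directed graph as (nodes, edge set), seeded by ``rng``."""
    n = int(rng.integers(n_min, n_max + 1))
    nodes = [f"v{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.05, min(0.6, 4.0 / n + 0.1)))
    edges = set()
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                edges.add((u, v))
    return nodes, edges
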