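"""Network controllers: hubs, hub subpopulations, bottlenecks, backbone.

Hubs are nodes whose degree is at least one standard deviation above the
network mean. Hubs split into subpopulations (classically "party" hubs,
low clustering coefficient, and "date" hubs, high clustering) detected as
modes of a kernel density estimate. Bottlenecks score how often a node
funnels the shortest-path trees of the network:

    BN(v) = sum over roots s of p_s(v),
    p_s(v) = 1  iff more than |V(T_s)|/4 paths of the tree T_s meet at v,

where "paths meeting at v" is read as the size of v's subtree (v plus its
descendants: every path to a descendant passes v, and the path ending at
v counts). The control backbone is the intersection of the hubs'
first-neighborhood network with the bottlenecks' first-neighborhood
network.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .graph_core import DirectedNetwork, EmptyNetworkError, intersect

# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------


@dataclass
class HubCriterion:
    """Degree threshold tau = mu + sigma_multiplier * sigma (population sigma)."""

    mean: float
    std: float
    threshold: float
    degree_kind: str = "degree"
    sigma_multiplier: float = 1.0


def identify_hubs(
    metrics: pd.DataFrame,
    sigma_multiplier: float = 1.0,
    degree_kind: str = "degree",
) -> tuple[HubCriterion, list[str]]:
    """Nodes with degree >= mean + sigma_multiplier * population std.

    The network is treated as a census, so sigma is the population
    standard deviation (ddof=0). The hub list is sorted by degree
    descending, ties broken lexicographically. When every node has the
    same degree sigma is zero and every node qualifies (with a warning).
    """
    if len(metrics) < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    degrees = metrics[degree_kind]
    mu = float(degrees.mean())
    sigma = float(degrees.std(ddof=0))
    tau = mu + sigma_multiplier * sigma
    crit = HubCriterion(
        mean=mu,
        std=sigma,
        threshold=tau,
        degree_kind=degree_kind,
        sigma_multiplier=sigma_multiplier,
    )
    hubs = degrees[degrees >= tau]
    if sigma == 0.0:
        warnings.warn(
            "all degrees equal: sigma = 0 makes every node a hub", stacklevel=2
        )
    ordered = sorted(hubs.items(), key=lambda kv: (-kv[1], kv[0]))
    return crit, [node for node, _deg in ordered]


# ---------------------------------------------------------------------------
# KDE subpopulations
# ---------------------------------------------------------------------------


@dataclass
class SubpopulationSplit:
    """Subpopulations of a metric found as modes of a Gaussian KDE.

    Boundaries are the strict local minima of the gridded density; value i
    belongs to subpopulation ``assignments[i]`` (intervals numbered left
    to right).
    """

    metric: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    boundaries: np.ndarray
    assignments: np.ndarray
    n_subpopulations: int
    degenerate: bool = False


def kde_split(
    values: Sequence[float],
    metric: str = "value",
    grid_size: int = 512,
    bandwidth: Optional[float] = None,
) -> SubpopulationSplit:
    """Split a sample into subpopulations separated by density minima.

    A Gaussian kernel density estimate with Silverman's rule-of-thumb
    bandwidth h = 0.9 * min(sd, IQR/1.34) * n^(-1/5) is evaluated on a
    uniform grid over [min - 3h, max + 3h]; each strict local minimum of
    the gridded density is a subpopulation boundary. A zero-variance
    sample yields a single degenerate subpopulation.
    """
    vals = np.asarray(list(values), dtype=float)
    n = len(vals)
    if n < 5:
        raise ValueError(f"kde_split needs >=5 values, got {n}")
    sd = float(vals.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(vals.mean()))):
        return SubpopulationSplit(
            metric=metric,
            grid=np.array([vals[0]]),
            density=np.array([np.inf]),
            bandwidth=0.0,
            boundaries=np.array([]),
            assignments=np.zeros(n, dtype=int),
            n_subpopulations=1,
            degenerate=True,
        )
    if bandwidth is None:
        q75, q25 = np.percentile(vals, [75, 25])
        iqr = q75 - q25
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * n ** (-1 / 5)
    h = float(bandwidth)
    grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, grid_size)
    z = (grid[:, None] - vals[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (n * h * np.sqrt(2 * np.pi))
    interior = np.flatnonzero(
        (density[1:-1] < density[:-2]) & (density[1:-1] < density[2:])
    )
    boundaries = grid[interior + 1]
    assignments = np.searchsorted(boundaries, vals)
    return SubpopulationSplit(
        metric=metric,
        grid=grid,
        density=density,
        bandwidth=h,
        boundaries=boundaries,
        assignments=assignments,
        n_subpopulations=len(boundaries) + 1,
    )


# ---------------------------------------------------------------------------
# shortest-path trees and bottlenecks
# ---------------------------------------------------------------------------


@dataclass
class ShortestPathTree:
    """BFS tree of shortest directed paths from ``root``.

    ``parent`` maps every reached non-root node to its tree parent; among
    equal-distance candidates the lexicographically smallest parent is
    chosen, so the tree is deterministic.
    """

    root: str
    parent: dict[str, str]

    @property
    def size(self) -> int:
        return len(self.parent) + 1

    @property
    def nodes(self) -> set[str]:
        return {self.root, *self.parent}


def shortest_path_tree(net: DirectedNetwork, root: str) -> ShortestPathTree:
    """Deterministic BFS shortest-path tree over directed edges."""
    if root not in net.nodes:
        raise KeyError(f"root {root!r} not in network")
    succ: dict[str, list[str]] = {}
    for s, t, _l in net.edge_keys():
        if s != t:
            succ.setdefault(s, []).append(t)
    dist = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in succ.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    parent: dict[str, str] = {}
    pred: dict[str, list[str]] = {}
    for u, d in dist.items():
        for v in succ.get(u, ()):
            if dist.get(v) == d + 1:
                pred.setdefault(v, []).append(u)
    for v, cands in pred.items():
        parent[v] = min(cands)
    return ShortestPathTree(root=root, parent=parent)


@dataclass
class BottleneckScores:
    """Per-node bottleneck counts BN(v) over all shortest-path-tree roots."""

    scores: dict[str, int]

    def top(self, k: int, degrees: Optional[Mapping[str, int]] = None) -> list[str]:
        return top_bottlenecks(self, k, degrees)


def _subtree_sizes(tree: ShortestPathTree) -> dict[str, int]:
    """Size of each node's subtree (the node plus its descendants)."""
    children: dict[str, list[str]] = {}
    for child, par in tree.parent.items():
        children.setdefault(par, []).append(child)
    sizes: dict[str, int] = {}
    # iterative post-order to stay safe on deep chains
    stack = [(tree.root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            sizes[node] = 1 + sum(sizes[c] for c in children.get(node, ()))
        else:
            stack.append((node, True))
            for c in children.get(node, ()):
                stack.append((c, False))
    return sizes


def root_indicators(net: DirectedNetwork, root: str) -> dict[str, int]:
    """The per-root indicator p_s(v) for every node v of T_root.

    p_s(v) = 1 iff the subtree of v holds more than |V(T_s)|/4 nodes;
    the root itself always scores 0 in its own tree.
    """
    tree = shortest_path_tree(net, root)
    sizes = _subtree_sizes(tree)
    quarter = tree.size / 4
    return {
        v: (1 if v != root and sizes[v] > quarter else 0) for v in tree.nodes
    }


def bottleneck_scores(net: DirectedNetwork) -> BottleneckScores:
    """BN(v) = number of roots whose shortest-path tree funnels through v."""
    if net.n_nodes == 0:
        raise EmptyNetworkError("bottleneck_scores of an empty network")
    bn = {node: 0 for node in net.nodes}
    for root in net.nodes:
        for v, p in root_indicators(net, root).items():
            bn[v] += p
    return BottleneckScores(scores=bn)


def top_bottlenecks(
    scores: BottleneckScores,
    k: int,
    degrees: Optional[Mapping[str, int]] = None,
) -> list[str]:
    """The k highest-BN nodes; ties break by degree, then lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(scores.scores)
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; returning all nodes", stacklevel=2)
        k = n
    deg = degrees or {}
    ordered = sorted(
        scores.scores.items(), key=lambda kv: (-kv[1], -deg.get(kv[0], 0), kv[0])
    )
    return [node for node, _ in ordered[:k]]


# ---------------------------------------------------------------------------
# control backbone
# ---------------------------------------------------------------------------


def neighborhood_network(net: DirectedNetwork, seeds: Iterable[str]) -> DirectedNetwork:
    """Induced subnetwork on ``seeds`` plus their first neighbors.

    Neighbors are taken in the undirected sense (in- or out-adjacent);
    all edges of the host network among the selected nodes are kept.
    """
    seed_set = set(seeds)
    selected = set(seed_set)
    for s, t, _l in net.edge_keys():
        if s in seed_set:
            selected.add(t)
        if t in seed_set:
            selected.add(s)
    return net.subnetwork(selected)


def control_backbone(
    net: DirectedNetwork,
    hubs: Sequence[str],
    bottlenecks: Sequence[str],
) -> DirectedNetwork:
    """Intersection of the hub and bottleneck neighborhood networks.

    This is the control backbone: the sub-network simultaneously within
    one step of a hub and one step of a bottleneck.
    """
    if not hubs or not bottlenecks:
        raise ValueError("hub and bottleneck lists must be non-empty")
    backbone = intersect(
        neighborhood_network(net, hubs), neighborhood_network(net, bottlenecks)
    )
    if backbone.n_nodes == 0:
        warnings.warn("hub and bottleneck neighborhoods do not overlap", stacklevel=2)
    return backbone
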