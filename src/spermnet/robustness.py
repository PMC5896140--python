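"""Failure and attack simulation on directed networks.

Scale-free networks are expected to be robust to random node failure
(a uniformly chosen node is almost surely not a hub) but fragile under
degree-targeted attack. The experiment removes a growing fraction of
nodes — cumulatively within a replicate, so the surviving network is
nested and the main-component size is monotone by construction — and
tracks the relative size S(f) of the largest weakly connected component
(normalized to the intact network's) and, optionally, the characteristic
path length among survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .graph_core import DirectedNetwork, EmptyNetworkError, percentage


@dataclass
class AttackCurve:
    """Result of a removal experiment.

    ``S`` has one row per replicate (a single row in targeted mode) and
    one column per removal fraction; entries are largest-component sizes
    relative to the intact network. ``cpl`` is NaN where not computed.
    """

    fractions: np.ndarray
    S: np.ndarray
    cpl: np.ndarray
    mode: str
    replicates: int
    seed: Optional[int]

    @property
    def mean_S(self) -> np.ndarray:
        return self.S.mean(axis=0)


def _largest_wcc_size(g: "nx.DiGraph") -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.weakly_connected_components(g))


def _cpl_sampled(g: "nx.DiGraph", rng: np.random.Generator, max_sources: int) -> float:
    """Characteristic path length estimated from BFS at sampled sources."""
    nodes = sorted(g)
    if len(nodes) < 2:
        return float("nan")
    if len(nodes) > max_sources:
        sources = list(rng.choice(nodes, size=max_sources, replace=False))
    else:
        sources = nodes
    total = count = 0
    for s in sources:
        for t, d in nx.single_source_shortest_path_length(g, s).items():
            if t != s:
                total += d
                count += 1
    return total / count if count else float("nan")


def attack(
    net: DirectedNetwork,
    mode: str = "random",
    fractions: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    replicates: int = 1,
    seed: Optional[int] = None,
    adaptive: bool = False,
    compute_cpl: bool = False,
    cpl_sources: int = 64,
) -> AttackCurve:
    """Simulate random failure or degree-targeted attack.

    Random mode removes uniformly sampled nodes, a fresh seeded permutation
    per replicate; targeted mode removes nodes in descending total-degree
    order computed on the intact network (``adaptive=True`` recomputes
    degrees after every removal instead). Removals are cumulative within a
    replicate, so S(f) is non-increasing by construction.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("attack on an empty network")
    fracs = np.asarray(list(fractions), dtype=float)
    if len(fracs) == 0 or np.any(fracs <= 0) or np.any(fracs >= 1):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    if np.any(np.diff(fracs) <= 0):
        raise ValueError("fractions must be strictly increasing")
    if mode not in ("random", "targeted"):
        raise ValueError(f"unknown mode {mode!r}")
    n = net.n_nodes
    removal_counts = [int(round(f * n)) for f in fracs]
    if removal_counts[-1] >= n:
        raise ValueError("largest fraction would remove every node")

    g0 = net.to_digraph()
    s0 = _largest_wcc_size(g0)
    rng = np.random.default_rng(seed)
    nodes_sorted = sorted(net.nodes)

    if mode == "targeted":
        replicates = 1
        if adaptive:
            orders = [None]  # computed on the fly below
        else:
            deg = dict(g0.degree())  # total (in+out) degree
            order = sorted(nodes_sorted, key=lambda v: (-deg[v], v))
            orders = [order]
    else:
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        orders = [
            list(rng.permutation(nodes_sorted)) for _ in range(replicates)
        ]

    S = np.zeros((len(orders), len(fracs)))
    cpl = np.full((len(orders), len(fracs)), np.nan)
    for rep, order in enumerate(orders):
        g = g0.copy()
        removed = 0
        for j, target_count in enumerate(removal_counts):
            while removed < target_count:
                if mode == "targeted" and adaptive:
                    victim = min(
                        g.nodes, key=lambda v: (-(g.in_degree(v) + g.out_degree(v)), v)
                    )
                else:
                    victim = order[removed]
                if g.has_node(victim):
                    g.remove_node(victim)
                removed += 1
            S[rep, j] = _largest_wcc_size(g) / s0
            if compute_cpl:
                cpl[rep, j] = _cpl_sampled(g, rng, cpl_sources)
    return AttackCurve(
        fractions=fracs,
        S=S,
        cpl=cpl,
        mode=mode,
        replicates=len(orders),
        seed=seed,
    )


def hub_hit_probability(hub_count: int, n_nodes: int) -> float:
    """Chance (percent, one decimal) that a uniform node removal hits a hub."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not (0 <= hub_count <= n_nodes):
        raise ValueError("hub_count must lie in [0, n_nodes]")
    return percentage(hub_count, n_nodes)
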