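"""Topology panel and degree-distribution power-law fits.

Path metrics (diameter, characteristic path length, betweenness,
reachable-pair census) respect edge direction; neighborhood metrics
(clustering coefficient, averaged neighbours) use the undirected view,
where the local clustering coefficient of node I is

    C_I = 2 n_I / (k_I (k_I - 1)),

with k_I the number of distinct neighbors (self excluded) and n_I the
number of links among them. A scale-free degree distribution follows
P(k) ~ k^(-gamma); gamma is estimated by ordinary least squares on the
log10-log10 degree histogram (the network-analyzer convention, reported
with Pearson r and R^2 = r^2), with a discrete maximum-likelihood
estimator available as an alternative method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import DirectedNetwork, EmptyNetworkError, connected_components, percentage


class InsufficientDataError(Exception):
    """Too few histogram bins or degree classes to fit."""


# ---------------------------------------------------------------------------
# per-node metrics
# ---------------------------------------------------------------------------


def node_metrics(net: DirectedNetwork) -> pd.DataFrame:
    """Per-node degree, clustering and betweenness table.

    Columns: ``in_degree``, ``out_degree``, ``degree`` (in + out; a
    self-loop adds one to each), ``neighbor_links`` (links among the
    undirected neighborhood, n_I), ``clustering`` (C_I, 0 when k_I < 2)
    and ``betweenness`` (directed, normalized by (N-1)(N-2)).
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("node_metrics of an empty network")
    g = net.to_digraph()
    u = net.to_undirected_simple()
    nodes = sorted(net.nodes)
    in_deg = dict(g.in_degree())
    out_deg = dict(g.out_degree())
    clustering = nx.clustering(u)
    triangles = nx.triangles(u)
    betweenness = (
        nx.betweenness_centrality(g, normalized=True)
        if net.n_nodes > 2
        else {n: 0.0 for n in nodes}
    )
    df = pd.DataFrame(
        {
            "in_degree": [in_deg[n] for n in nodes],
            "out_degree": [out_deg[n] for n in nodes],
            "degree": [in_deg[n] + out_deg[n] for n in nodes],
            "neighbor_links": [triangles[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return df


# ---------------------------------------------------------------------------
# network-level report
# ---------------------------------------------------------------------------


@dataclass
class TopologyReport:
    """The standard topology panel for one directed network."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    n_components: int
    diameter: int
    shortest_path_count: int
    shortest_path_pct: float
    characteristic_path_length: float
    avg_neighbours: float

    def to_dict(self) -> dict:
        return {
            "number_of_nodes": self.n_nodes,
            "number_of_edges": self.n_edges,
            "clustering_coefficient": self.clustering_coefficient,
            "connected_components": self.n_components,
            "network_diameter": self.diameter,
            "shortest_paths": self.shortest_path_count,
            "shortest_paths_pct": self.shortest_path_pct,
            "characteristic_path_length": self.characteristic_path_length,
            "avg_number_of_neighbours": self.avg_neighbours,
        }


def topology_report(net: DirectedNetwork) -> TopologyReport:
    """Compute the topology panel by BFS from every node.

    Shortest paths run along edge direction; the diameter is the longest
    finite shortest path, the characteristic path length the mean over
    reachable ordered pairs (n != m), and the shortest-path percentage the
    share of the N(N-1) ordered pairs that are reachable (one decimal).
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("topology_report of an empty network")
    g = net.to_digraph()
    n = net.n_nodes
    n_pairs = 0
    total_len = 0
    diameter = 0
    for source in g:
        lengths = nx.single_source_shortest_path_length(g, source)
        for target, dist in lengths.items():
            if target == source:
                continue
            n_pairs += 1
            total_len += dist
            if dist > diameter:
                diameter = dist
    cpl = total_len / n_pairs if n_pairs else float("nan")
    pct = percentage(n_pairs, n * (n - 1)) if n > 1 else 0.0

    u = net.to_undirected_simple()
    avg_neigh = sum(d for _n, d in u.degree()) / n
    mean_clust = float(np.mean(list(nx.clustering(u).values())))

    return TopologyReport(
        n_nodes=n,
        n_edges=net.n_edges,
        clustering_coefficient=mean_clust,
        n_components=connected_components(net).n_components,
        diameter=diameter,
        shortest_path_count=n_pairs,
        shortest_path_pct=pct,
        characteristic_path_length=cpl,
        avg_neighbours=avg_neigh,
    )


# ---------------------------------------------------------------------------
# degree distributions and power-law fits
# ---------------------------------------------------------------------------


@dataclass
class DegreeHistogram:
    """Histogram of a degree flavor: counts over observed k >= 1.

    Zero-degree nodes are tallied separately so that
    ``sum(counts.values()) + zero_degree_count == n``.
    """

    counts: dict[int, int]
    zero_degree_count: int
    n: int
    which: str

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) + self.zero_degree_count == self.n


def degree_distribution(
    metrics: pd.DataFrame, which: Literal["in", "out", "total"] = "total"
) -> DegreeHistogram:
    """Degree histogram from a :func:`node_metrics` table."""
    col = {"in": "in_degree", "out": "out_degree", "total": "degree"}[which]
    values = metrics[col].to_numpy()
    ks, counts = np.unique(values, return_counts=True)
    d = {int(k): int(c) for k, c in zip(ks, counts) if k >= 1}
    zero = int(counts[ks == 0].sum()) if (ks == 0).any() else 0
    return DegreeHistogram(counts=d, zero_degree_count=zero, n=len(values), which=which)


@dataclass
class PowerLawFit:
    """Fitted exponent of P(k) ~ k^(-gamma) plus fit-quality statistics.

    ``gamma`` is reported signed as the slope of the log-log fit (negative
    for decaying distributions). ``r`` is the Pearson correlation of the
    logged pairs and ``r_squared = r**2``; both are NaN for the maximum-
    likelihood method, which has no regression-quality analogue.
    """

    gamma: float
    r: float
    r_squared: float
    fitted_on: str
    method: str = "ols"
    n_points: int = 0
    degenerate: bool = False


def fit_power_law(
    hist: DegreeHistogram | Mapping[int, float],
    method: Literal["ols", "mle"] = "ols",
    k_min: Optional[int] = None,
) -> PowerLawFit:
    """Fit the degree-distribution exponent.

    ``ols`` (default): ordinary least squares of log10(count) on log10(k)
    over bins with count >= 1, slope reported as gamma, with Pearson r and
    R^2 = r^2. ``mle``: discrete power-law maximum likelihood (Clauset
    approximation) on degrees >= ``k_min`` (default: smallest observed k);
    gamma is reported negative to keep one sign convention across methods.
    """
    if isinstance(hist, DegreeHistogram):
        counts = hist.counts
        label = hist.which
    else:
        counts = {int(k): v for k, v in hist.items()}
        label = "histogram"
    pairs = sorted((k, c) for k, c in counts.items() if k >= 1 and c >= 1)
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >=3 non-zero bins, got {len(pairs)}")

    if method == "mle":
        kmin = k_min if k_min is not None else pairs[0][0]
        ks = np.array([k for k, _ in pairs if k >= kmin], dtype=float)
        cs = np.array([c for k, c in pairs if k >= kmin], dtype=float)
        if len(ks) < 3:
            raise InsufficientDataError("need >=3 bins at or above k_min")
        n = cs.sum()
        gamma_hat = 1.0 + n / float(np.sum(cs * np.log(ks / (kmin - 0.5))))
        return PowerLawFit(
            gamma=-gamma_hat,
            r=float("nan"),
            r_squared=float("nan"),
            fitted_on=label,
            method="mle",
            n_points=int(n),
        )

    log_k = np.log10([k for k, _ in pairs])
    log_c = np.log10([c for _, c in pairs])
    if np.allclose(log_c, log_c[0]):
        # flat histogram: slope 0, correlation undefined
        return PowerLawFit(
            gamma=0.0,
            r=0.0,
            r_squared=0.0,
            fitted_on=label,
            n_points=len(pairs),
            degenerate=True,
        )
    res = stats.linregress(log_k, log_c)
    return PowerLawFit(
        gamma=float(res.slope),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        fitted_on=label,
        n_points=len(pairs),
    )


def clustering_vs_degree(metrics: pd.DataFrame) -> PowerLawFit:
    """Fit mean clustering coefficient per degree class against k, log-log.

    In a preferential-attachment network C(k) is roughly independent of k
    (slope near 0, low R^2); hierarchical networks show C(k) ~ k^-1.
    """
    grouped = metrics.groupby("degree")["clustering"].mean()
    grouped = grouped[(grouped.index >= 1) & (grouped > 0)]
    if len(grouped) < 3:
        if (metrics["clustering"] == 0).all():
            return PowerLawFit(
                gamma=0.0,
                r=0.0,
                r_squared=0.0,
                fitted_on="C(k)-vs-k",
                n_points=0,
                degenerate=True,
            )
        raise InsufficientDataError(
            f"need >=3 degree classes with mean C(k) > 0, got {len(grouped)}"
        )
    log_k = np.log10(grouped.index.to_numpy(dtype=float))
    log_c = np.log10(grouped.to_numpy())
    if np.allclose(log_c, log_c[0]):
        return PowerLawFit(
            gamma=0.0,
            r=0.0,
            r_squared=0.0,
            fitted_on="C(k)-vs-k",
            n_points=len(grouped),
            degenerate=True,
        )
    res = stats.linregress(log_k, log_c)
    return PowerLawFit(
        gamma=float(res.slope),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        fitted_on="C(k)-vs-k",
        n_points=len(grouped),
    )
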