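"""Directed-network data model, file dialects and set algebra.

The interactome is modelled as a directed graph whose nodes are molecules
(proteins, metabolites, reactions) and whose links are pathway interactions.
Edges carry an interaction label and, optionally, an integer confidence
score on the 0-1000 scale used by protein-association databases.

Two text dialects are supported: Cytoscape SIF (``source relation target``,
whitespace-separated) and TSV edge lists with 2 columns (source, target),
3 columns (source, interaction, target) or 4 columns (plus score).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: default interaction label for unlabeled edge lists
DEFAULT_INTERACTION = "pp"

_TSV_HEADER = ("source", "interaction", "target", "score")


class NetworkError(Exception):
    """Base class for network model errors."""


class NetworkParseError(NetworkError):
    """A row of a network file could not be interpreted."""


class EmptyNetworkError(NetworkError):
    """An operation that requires a non-empty network received an empty one."""


@dataclass(frozen=True)
class EdgeRecord:
    """One directed interaction: source --interaction--> target.

    ``score`` is an optional confidence on the integer 0-1000 scale.
    """

    source: str
    interaction: str
    target: str
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty strings")
        if self.score is not None and not (0 <= self.score <= 1000):
            raise ValueError(f"score {self.score} outside [0, 1000]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.interaction)


class DirectedNetwork:
    """A directed network with labelled, optionally scored edges.

    Duplicate (source, target, label) triples collapse to a single edge;
    when duplicates carry different scores the maximum is kept (a
    confidence semantics: the best evidence wins). Self-loops are legal
    but flagged via :attr:`self_loops`.
    """

    def __init__(
        self,
        edges: Iterable[EdgeRecord] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self._edges: dict[tuple[str, str, str], Optional[int]] = {}
        self._nodes: set[str] = set(nodes)
        for rec in edges:
            self.add_edge(rec)

    # -- construction ---------------------------------------------------

    def add_edge(self, rec: EdgeRecord) -> None:
        key = rec.key
        if key in self._edges:
            old = self._edges[key]
            new = rec.score
            if old != new:
                best = max((s for s in (old, new) if s is not None), default=None)
                logger.debug("collapsing duplicate edge %s, keeping score %s", key, best)
                self._edges[key] = best
        else:
            self._edges[key] = rec.score
        self._nodes.add(rec.source)
        self._nodes.add(rec.target)

    def add_node(self, node: str) -> None:
        if not node:
            raise ValueError("node id must be a non-empty string")
        self._nodes.add(node)

    # -- views ----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def self_loops(self) -> frozenset[str]:
        """Nodes with an edge onto themselves."""
        return frozenset(s for (s, t, _l) in self._edges if s == t)

    def edges(self) -> Iterator[EdgeRecord]:
        for (s, t, label), score in self._edges.items():
            yield EdgeRecord(s, label, t, score)

    def sorted_edges(self) -> list[EdgeRecord]:
        return sorted(self.edges(), key=lambda e: e.key)

    def has_edge(self, source: str, target: str, interaction: Optional[str] = None) -> bool:
        if interaction is not None:
            return (source, target, interaction) in self._edges
        return any(k[0] == source and k[1] == target for k in self._edges)

    def edge_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __len__(self) -> int:
        return self.n_nodes

    def __repr__(self) -> str:
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- conversions ----------------------------------------------------

    def to_digraph(self) -> "nx.DiGraph":
        """Project onto a simple directed graph (parallel labels collapse)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for (s, t, label), score in self._edges.items():
            g.add_edge(s, t, interaction=label, score=score)
        return g

    def to_undirected_simple(self, drop_self_loops: bool = True) -> "nx.Graph":
        """Undirected simple view: direction and parallel labels ignored.

        Self-loops are dropped by default, as required for neighborhood and
        clustering computations.
        """
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for (s, t, _label) in self._edges:
            if drop_self_loops and s == t:
                continue
            g.add_edge(s, t)
        return g

    def subnetwork(self, keep: Iterable[str]) -> "DirectedNetwork":
        """Induced subnetwork on ``keep`` (edges with both endpoints kept)."""
        keep_set = set(keep)
        sub = DirectedNetwork(nodes=keep_set & self._nodes)
        for rec in self.edges():
            if rec.source in keep_set and rec.target in keep_set:
                sub.add_edge(rec)
        return sub


@dataclass
class ComponentDecomposition:
    """Weakly connected components, largest first.

    ``components`` partition the node set; ties in size are broken by the
    lexicographically smallest member.
    """

    components: list[frozenset[str]]
    main_index: int = 0

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def main(self) -> frozenset[str]:
        return self.components[self.main_index]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _parse_score(token: str, path: str, lineno: int) -> int:
    try:
        score = int(token)
    except ValueError as exc:
        raise NetworkParseError(f"{path}:{lineno}: score {token!r} is not an integer") from exc
    if not (0 <= score <= 1000):
        raise NetworkParseError(f"{path}:{lineno}: score {score} outside [0, 1000]")
    return score


def read_network(path: str | Path, dialect: str = "sif") -> DirectedNetwork:
    """Read a directed network from a SIF or TSV edge-list file.

    Parameters
    ----------
    path:
        File to read (UTF-8 text).
    dialect:
        ``"sif"`` for whitespace-separated ``source relation target`` rows,
        ``"tsv"`` for tab-separated rows with 2, 3 or 4 columns. A TSV
        header row ``source  interaction  target  [score]`` is skipped.

    Raises
    ------
    NetworkParseError
        On a malformed row (the message names the line number).
    EmptyNetworkError
        When the file contains no rows.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = DirectedNetwork()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "sif":
                fields = line.split()
                if len(fields) != 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: SIF row must have 3 whitespace-separated "
                        f"fields, got {len(fields)}"
                    )
                src, label, tgt = fields
                score = None
            else:
                fields = line.split("\t")
                if lineno == 1 and tuple(f.lower() for f in fields) in (
                    _TSV_HEADER[:2],
                    _TSV_HEADER[:3],
                    _TSV_HEADER,
                    ("source", "target"),
                    ("source", "target", "score"),
                ):
                    continue
                if len(fields) == 2:
                    src, tgt = fields
                    label, score = DEFAULT_INTERACTION, None
                elif len(fields) == 3:
                    src, label, tgt = fields
                    score = None
                elif len(fields) == 4:
                    src, label, tgt = fields[:3]
                    score = _parse_score(fields[3], str(path), lineno) if fields[3] else None
                else:
                    raise NetworkParseError(
                        f"{path}:{lineno}: TSV row must have 2-4 tab-separated "
                        f"fields, got {len(fields)}"
                    )
            if not src or not tgt or not label:
                raise NetworkParseError(f"{path}:{lineno}: empty field in row {line!r}")
            net.add_edge(EdgeRecord(src, label, tgt, score))
            n_rows += 1
    if n_rows == 0:
        raise EmptyNetworkError(f"{path}: no edge rows found")
    return net


def write_network(net: DirectedNetwork, path: str | Path, dialect: str = "sif") -> None:
    """Write a network in SIF or 4-column TSV form (sorted, reproducible).

    Isolated nodes are not representable in either edge-list dialect and are
    dropped with a warning; an empty network produces an empty file with a
    warning.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if net.n_edges == 0:
        warnings.warn(f"writing empty network to {path}", stacklevel=2)
    covered = {e.source for e in net.edges()} | {e.target for e in net.edges()}
    isolated = net.nodes - covered
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated node(s) not representable in {dialect} "
            "edge list, dropped",
            stacklevel=2,
        )
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_HEADER) + "\n")
        for rec in net.sorted_edges():
            if dialect == "sif":
                fh.write(f"{rec.source} {rec.interaction} {rec.target}\n")
            else:
                score = "" if rec.score is None else str(rec.score)
                fh.write(f"{rec.source}\t{rec.interaction}\t{rec.target}\t{score}\n")


def write_graphml(net: DirectedNetwork, path: str | Path) -> None:
    """Export to GraphML for external viewers (preserves isolated nodes)."""
    g = net.to_digraph()
    for _u, _v, data in g.edges(data=True):
        if data.get("score") is None:
            data.pop("score", None)
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# set algebra and components
# ---------------------------------------------------------------------------


def connected_components(net: DirectedNetwork) -> ComponentDecomposition:
    """Weakly connected components, ordered by decreasing size.

    Direction is ignored for membership; size ties break by the
    lexicographically smallest member so the ordering is deterministic.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot decompose an empty network")
    comps = [frozenset(c) for c in nx.weakly_connected_components(net.to_digraph())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentDecomposition(components=comps, main_index=0)


def main_component(net: DirectedNetwork) -> DirectedNetwork:
    """Induced subnetwork on the largest weakly connected component."""
    decomp = connected_components(net)
    return net.subnetwork(decomp.main)


def main_component_share(net: DirectedNetwork) -> float:
    """Percentage of nodes in the main component, to one decimal."""
    decomp = connected_components(net)
    return percentage(len(decomp.main), net.n_nodes)


def percentage(part: int | float, whole: int | float, decimals: int = 1) -> float:
    """100*part/whole with round-half-up at ``decimals`` places."""
    if whole == 0:
        raise ValueError("percentage of an empty total is undefined")
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(str(part)) / Decimal(str(whole))).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def intersect(net1: DirectedNetwork, net2: DirectedNetwork) -> DirectedNetwork:
    """Node and edge intersection of two networks.

    Nodes are the node-set intersection; edges must be present in both
    (by source, target and label) with both endpoints surviving. When the
    two copies of an edge disagree on score, the maximum is kept.
    """
    nodes = net1.nodes & net2.nodes
    out = DirectedNetwork(nodes=nodes)
    keys2 = net2.edge_keys()
    for rec in net1.edges():
        if rec.key in keys2 and rec.source in nodes and rec.target in nodes:
            out.add_edge(rec)
    for rec in net2.edges():
        if rec.key in out.edge_keys():
            out.add_edge(rec)  # max-score collapse
    return out


def union_merge(nets: Sequence[DirectedNetwork]) -> DirectedNetwork:
    """Union of node and edge sets with duplicate collapse (max score)."""
    if len(nets) == 0:
        raise ValueError("union_merge requires at least one network")
    out = DirectedNetwork()
    for net in nets:
        for node in net.nodes:
            out.add_node(node)
        for rec in net.edges():
            out.add_edge(rec)
    return out
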