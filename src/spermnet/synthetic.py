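"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline end to end without any database
access:

* a directed preferential-attachment (Barabasi-Albert) network — new
  nodes attach to existing node i with probability k_i / sum_j k_j, so
  the degree distribution is scale-free;
* a fragmentation step that emulates how such a network reaches the
  pipeline in practice: overlapping pathway edge lists with aliased
  node identifiers plus a scored enrichment table — assembling the
  fragments must reconstruct the source network;
* knockout-phenotype annotation tables drawn from per-class
  multinomials, and planted "party"/"date" clustering-coefficient
  samples (uniform on [0, 0.17] and [0.83, 0.89]) for subpopulation
  detection.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .assembly import AliasMap
from .graph_core import DirectedNetwork, EdgeRecord, write_network

#: Table-style multinomial defaults for knockout phenotype simulation
HUB_PHENOTYPE_PROBS = (0.238, 0.143, 0.143, 0.476)
NONHUB_PHENOTYPE_PROBS = (0.278, 0.174, 0.275, 0.272)

PARTY_RANGE = (0.0, 0.17)
DATE_RANGE = (0.83, 0.89)


# ---------------------------------------------------------------------------
# preferential attachment
# ---------------------------------------------------------------------------


@dataclass
class BAGeneratorConfig:
    """Growth parameters of the preferential-attachment generator.

    The seed graph is a complete symmetric clique on ``m0`` nodes (both
    directions of every pair), which avoids zero-degree attachment
    pathologies; every arriving node then links to ``m`` distinct
    existing nodes, chosen with probability proportional to current
    total degree, edges directed new -> target.
    """

    n_nodes: int
    m: int = 2
    m0: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.m0 is None:
            self.m0 = self.m + 1
        if self.m0 < self.m:
            raise ValueError("seed clique size m0 must be >= m")
        if self.n_nodes <= self.m0:
            raise ValueError("n_nodes must exceed the seed clique size")


def _node_name(i: int, n: int) -> str:
    return f"n{i:0{len(str(n - 1))}d}"


def generate_ba(config: BAGeneratorConfig) -> DirectedNetwork:
    """Grow a directed scale-free network by preferential attachment."""
    n, m, m0 = config.n_nodes, config.m, config.m0
    rng = np.random.default_rng(config.seed)
    net = DirectedNetwork()
    degree = np.zeros(n, dtype=np.int64)
    names = [_node_name(i, n) for i in range(n)]
    for i in range(m0):
        for j in range(m0):
            if i != j:
                net.add_edge(EdgeRecord(names[i], "pp", names[j]))
        degree[i] = 2 * (m0 - 1)
    for new in range(m0, n):
        cum = np.cumsum(degree[:new])
        targets: set[int] = set()
        # sequential draws with rejection of repeats: exact for m << N
        while len(targets) < m:
            r = int(rng.integers(0, cum[-1]))
            targets.add(int(np.searchsorted(cum, r, side="right")))
        for t in sorted(targets):
            net.add_edge(EdgeRecord(names[new], "pp", names[t]))
            degree[t] += 1
            degree[new] += 1
    return net


# ---------------------------------------------------------------------------
# fragmentation into pipeline inputs
# ---------------------------------------------------------------------------


@dataclass
class FragmentationConfig:
    """How to shatter a network into assembly inputs.

    ``coverage`` is the edge fraction each pathway file holds (every edge
    is assigned to at least one pathway regardless, so the union always
    covers the network); ``alias_fraction`` of the nodes receive a
    synonym in a random subset of their fragments; the enrichment table
    holds ``n_enrichment`` scored within-network pairs of which
    ``enrichment_above_fraction`` score above 900.
    """

    n_pathways: int = 32
    coverage: float = 0.05
    alias_fraction: float = 0.1
    n_enrichment: int = 100
    enrichment_above_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must lie in (0, 1]")
        if not (0 <= self.alias_fraction <= 1):
            raise ValueError("alias_fraction must lie in [0, 1]")
        if not (0 <= self.enrichment_above_fraction <= 1):
            raise ValueError("enrichment_above_fraction must lie in [0, 1]")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")


@dataclass
class FragmentationResult:
    """Pathway fragments, alias table and enrichment table for assembly."""

    fragments: list[DirectedNetwork]
    alias_map: AliasMap
    enrichment: list[EdgeRecord]
    n_above_threshold: int
    source_nodes: int
    source_edges: int

    def write(self, outdir: str | Path) -> dict[str, list[str] | str]:
        """Write fragments (TSV), alias table and enrichment table.

        Returns the file paths, ready to feed an
        :class:`~spermnet.assembly.AssemblyConfig`.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frag_paths = []
        for i, frag in enumerate(self.fragments):
            p = outdir / f"pathway_{i:02d}.tsv"
            write_network(frag, p, dialect="tsv")
            frag_paths.append(str(p))
        alias_path = outdir / "aliases.tsv"
        self.alias_map.to_tsv(alias_path)
        enr_path = outdir / "enrichment.tsv"
        with open(enr_path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tscore\n")
            for rec in self.enrichment:
                fh.write(f"{rec.source}\t{rec.target}\t{rec.score}\n")
        return {
            "pathways": frag_paths,
            "aliases": str(alias_path),
            "enrichment": str(enr_path),
        }


def fragment(net: DirectedNetwork, config: FragmentationConfig) -> FragmentationResult:
    """Shatter a network into overlapping, partially aliased pathway files.

    Every edge lands in at least one fragment; fragments are then topped
    up with extra edges until each holds ``coverage`` of the edge set, so
    neighboring pathways overlap as real pathway exports do. Aliased
    nodes are renamed (suffix ``.syn``) within a random subset of their
    fragments; the alias table undoes the renaming. Enrichment pairs are
    sampled among existing edges so that a strict >900 filter adds
    nothing new: assembling the output reconstructs ``net`` exactly
    whenever ``enrichment_above_fraction`` is zero.
    """
    if net.n_edges == 0:
        raise ValueError("cannot fragment a network with no edges")
    rng = np.random.default_rng(config.seed)
    edges = net.sorted_edges()
    n_edges = len(edges)
    p = config.n_pathways

    assignment = rng.integers(0, p, size=n_edges)
    per_pathway: list[set[int]] = [set() for _ in range(p)]
    for idx, path_i in enumerate(assignment):
        per_pathway[path_i].add(int(idx))
    target_size = min(n_edges, max(1, math.ceil(config.coverage * n_edges)))
    for path_i in range(p):
        want = target_size - len(per_pathway[path_i])
        if want > 0:
            pool = [i for i in range(n_edges) if i not in per_pathway[path_i]]
            extra = rng.choice(len(pool), size=min(want, len(pool)), replace=False)
            per_pathway[path_i].update(pool[int(e)] for e in extra)

    nodes_sorted = sorted(net.nodes)
    n_aliased = int(round(config.alias_fraction * len(nodes_sorted)))
    aliased = set(
        rng.choice(nodes_sorted, size=n_aliased, replace=False).tolist()
        if n_aliased
        else []
    )
    alias_of = {node: f"{node}.syn" for node in aliased}

    fragments: list[DirectedNetwork] = []
    for path_i in range(p):
        frag = DirectedNetwork()
        # which aliased nodes show their synonym in this fragment
        use_alias = {node for node in aliased if rng.random() < 0.5}
        for idx in sorted(per_pathway[path_i]):
            rec = edges[idx]
            s = alias_of[rec.source] if rec.source in use_alias else rec.source
            t = alias_of[rec.target] if rec.target in use_alias else rec.target
            frag.add_edge(EdgeRecord(s, rec.interaction, t, rec.score))
        fragments.append(frag)

    n_above = int(round(config.enrichment_above_fraction * config.n_enrichment))
    enrichment: list[EdgeRecord] = []
    if config.n_enrichment > 0:
        picks = rng.integers(0, n_edges, size=config.n_enrichment)
        for i, idx in enumerate(picks):
            rec = edges[int(idx)]
            if i < n_above:
                score = int(rng.integers(901, 1001))
            else:
                score = int(rng.integers(0, 901))
            enrichment.append(EdgeRecord(rec.source, "string", rec.target, score))
    return FragmentationResult(
        fragments=fragments,
        alias_map=AliasMap(alias_of_inverse(alias_of)),
        enrichment=enrichment,
        n_above_threshold=n_above,
        source_nodes=net.n_nodes,
        source_edges=net.n_edges,
    )


def alias_of_inverse(alias_of: dict[str, str]) -> dict[str, str]:
    """Turn canonical -> synonym into the alias-table direction."""
    return {syn: canon for canon, syn in alias_of.items()}


# ---------------------------------------------------------------------------
# phenotype simulation and planted hub metrics
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeSimConfig:
    """Multinomial phenotype simulation parameters.

    Per-class probabilities over the four fertility categories (slightly
    off-unit vectors from printed rounding are renormalized) and the
    per-class fraction of nodes with knockout data.
    """

    hub_probs: Sequence[float] = HUB_PHENOTYPE_PROBS
    nonhub_probs: Sequence[float] = NONHUB_PHENOTYPE_PROBS
    hub_data_fraction: float = 0.356
    nonhub_data_fraction: float = 0.196
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for probs in (self.hub_probs, self.nonhub_probs):
            if len(probs) != 4 or any(p < 0 for p in probs):
                raise ValueError("need 4 non-negative category probabilities")
            if not math.isclose(sum(probs), 1.0, abs_tol=0.005):
                raise ValueError(f"probabilities sum to {sum(probs)}, not 1")
        for f in (self.hub_data_fraction, self.nonhub_data_fraction):
            if not (0 <= f <= 1):
                raise ValueError("data fractions must lie in [0, 1]")


def simulate_phenotypes(
    hubs: Sequence[str],
    non_hubs: Sequence[str],
    config: PhenotypeSimConfig,
) -> dict[str, str]:
    """Draw knockout phenotypes for a sampled subset of each node class."""
    from .phenotype_stats import CATEGORIES

    overlap = set(hubs) & set(non_hubs)
    if overlap:
        raise ValueError(f"hub and non-hub lists overlap: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(config.seed)
    annotations: dict[str, str] = {}
    for nodes, probs, fraction in (
        (sorted(hubs), config.hub_probs, config.hub_data_fraction),
        (sorted(non_hubs), config.nonhub_probs, config.nonhub_data_fraction),
    ):
        if not nodes:
            continue
        n_studied = int(round(fraction * len(nodes)))
        studied = rng.choice(nodes, size=n_studied, replace=False) if n_studied else []
        pvec = np.asarray(probs, dtype=float)
        pvec = pvec / pvec.sum()
        cats = rng.choice(len(CATEGORIES), size=len(studied), p=pvec)
        for node, ci in zip(studied, cats):
            annotations[str(node)] = CATEGORIES[int(ci)]
    return annotations


def planted_hub_metrics(
    n_party: int, n_date: int, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Clustering-coefficient sample with planted party/date subpopulations.

    Party values are uniform on [0, 0.17], date values on [0.83, 0.89].
    Returns ``(values, labels)`` with label 0 for party and 1 for date —
    the labels are the ground truth for subpopulation-recovery checks.
    """
    if n_party < 0 or n_date < 0:
        raise ValueError("sample sizes must be non-negative")
    rng = np.random.default_rng(seed)
    party = rng.uniform(*PARTY_RANGE, size=n_party)
    date = rng.uniform(*DATE_RANGE, size=n_date)
    values = np.concatenate([party, date])
    labels = np.concatenate([np.zeros(n_party, dtype=int), np.ones(n_date, dtype=int)])
    return values, labels
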