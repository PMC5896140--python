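"""Network assembly: pathway merge, alias harmonization, scored enrichment.

Mirrors the construction of a pathway-based interactome: overlapping
pathway edge lists are unioned, molecule identifiers are harmonized
against an alias table (synonyms collapse onto one canonical ID), and
the result is enriched with externally scored association edges kept
only above a confidence threshold (strictly greater than, default 900
on the 0-1000 scale) and only between molecules already in the network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .graph_core import (
    DEFAULT_INTERACTION,
    DirectedNetwork,
    EdgeRecord,
    read_network,
    union_merge,
)

logger = logging.getLogger(__name__)


class AliasConfigError(Exception):
    """The alias table violates its contract (chains or cycles)."""


class AliasMap:
    """Mapping from alias IDs to canonical IDs.

    Canonical IDs are fixed points: an ID that appears as a canonical
    target may never itself be mapped elsewhere, so resolution is a
    single lookup and chains or cycles in the input table are rejected
    up front.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = dict(mapping or {})
        self._validate()

    def _validate(self) -> None:
        offenders = [
            alias
            for alias, canon in self._map.items()
            if canon in self._map and self._map[canon] != canon
        ]
        if offenders:
            raise AliasConfigError(
                "alias table contains chains/cycles via: " + ", ".join(sorted(offenders))
            )
        # drop identity rows
        self._map = {a: c for a, c in self._map.items() if a != c}

    def resolve(self, node: str) -> str:
        return self._map.get(node, node)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Read a two-column ``alias<TAB>canonical`` table (optional header)."""
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if lineno == 1 and [f.lower() for f in fields] == ["alias", "canonical"]:
                    continue
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise AliasConfigError(f"{path}:{lineno}: expected 'alias<TAB>canonical'")
                mapping[fields[0]] = fields[1]
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("alias\tcanonical\n")
            for alias, canon in sorted(self._map.items()):
                fh.write(f"{alias}\t{canon}\n")


def harmonize(net: DirectedNetwork, aliases: AliasMap) -> DirectedNetwork:
    """Rename every node to its canonical ID and collapse the duplicates.

    Merged nodes inherit the union of incident edges; the node count never
    increases. Idempotent: a second pass is the identity.
    """
    out = DirectedNetwork()
    for node in net.nodes:
        out.add_node(aliases.resolve(node))
    for rec in net.edges():
        out.add_edge(
            EdgeRecord(
                aliases.resolve(rec.source),
                rec.interaction,
                aliases.resolve(rec.target),
                rec.score,
            )
        )
    return out


def filter_interactions(
    edges: Iterable[EdgeRecord], min_score: int = 900
) -> list[EdgeRecord]:
    """Keep records with score strictly greater than ``min_score``.

    Order is preserved. Records without a score cannot certify their
    confidence and are dropped with a warning.
    """
    if not (0 <= min_score <= 1000):
        raise ValueError(f"min_score {min_score} outside [0, 1000]")
    kept: list[EdgeRecord] = []
    n_unscored = 0
    for rec in edges:
        if rec.score is None:
            n_unscored += 1
            continue
        if rec.score > min_score:
            kept.append(rec)
    if n_unscored:
        warnings.warn(
            f"{n_unscored} enrichment record(s) lack a confidence score and were dropped",
            stacklevel=2,
        )
    return kept


def read_enrichment_table(path: str | Path) -> list[EdgeRecord]:
    """Read a scored association table ``source<TAB>target<TAB>score``.

    The associations are undirected evidence; direction is applied at
    assembly time.
    """
    records: list[EdgeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.lower() for f in fields][:2] == ["source", "target"]:
                continue
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected source, target[, score]")
            score = int(fields[2]) if len(fields) == 3 and fields[2] else None
            records.append(EdgeRecord(fields[0], "string", fields[1], score))
    return records


@dataclass
class AssemblyConfig:
    """Inputs of the three-stage assembly.

    ``min_score`` is a strict lower bound on the enrichment confidence
    score (0-1000); the default keeps only scores > 900.
    """

    pathway_files: Sequence[str | Path] = field(default_factory=list)
    alias_file: Optional[str | Path] = None
    enrichment_file: Optional[str | Path] = None
    min_score: int = 900
    dialect: str = "tsv"

    def __post_init__(self) -> None:
        if not (0 <= self.min_score <= 1000):
            raise ValueError(f"min_score {self.min_score} outside [0, 1000]")


def assemble(
    config: AssemblyConfig | None = None,
    *,
    pathways: Sequence[DirectedNetwork] | None = None,
    aliases: AliasMap | None = None,
    enrichment: Sequence[EdgeRecord] | None = None,
    min_score: int = 900,
) -> DirectedNetwork:
    """Run pathway union -> harmonization -> score-filtered enrichment.

    Accepts either an :class:`AssemblyConfig` naming files on disk or
    in-memory objects via keyword arguments. Enrichment associations are
    undirected evidence: each surviving pair adds both directions, and
    only pairs whose endpoints already exist in the harmonized union are
    admitted (enrichment completes the network, it does not expand it).
    Per-stage node/edge counts are logged.
    """
    if config is not None:
        pathways = [read_network(p, dialect=config.dialect) for p in config.pathway_files]
        aliases = AliasMap.from_tsv(config.alias_file) if config.alias_file else None
        enrichment = (
            read_enrichment_table(config.enrichment_file) if config.enrichment_file else None
        )
        min_score = config.min_score
    if not pathways:
        raise ValueError("assemble requires at least one pathway network")

    merged = union_merge(list(pathways))
    logger.info("pathway union: %d nodes, %d edges", merged.n_nodes, merged.n_edges)

    harmonized = harmonize(merged, aliases or AliasMap())
    logger.info("harmonized: %d nodes, %d edges", harmonized.n_nodes, harmonized.n_edges)

    result = union_merge([harmonized])
    n_added = n_rejected = 0
    if enrichment:
        surviving = filter_interactions(list(enrichment), min_score=min_score)
        alias_map = aliases or AliasMap()
        nodes = harmonized.nodes
        for rec in surviving:
            s = alias_map.resolve(rec.source)
            t = alias_map.resolve(rec.target)
            if s in nodes and t in nodes:
                # undirected association: both directions enter the network
                result.add_edge(EdgeRecord(s, rec.interaction, t, rec.score))
                result.add_edge(EdgeRecord(t, rec.interaction, s, rec.score))
                n_added += 1
            else:
                n_rejected += 1
        if n_rejected:
            warnings.warn(
                f"{n_rejected} enrichment pair(s) reference nodes absent from the "
                "pathway union and were dropped",
                stacklevel=2,
            )
    logger.info(
        "enriched: %d nodes, %d edges (%d pairs added, %d rejected)",
        result.n_nodes,
        result.n_edges,
        n_added,
        n_rejected,
    )
    return result
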