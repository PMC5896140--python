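"""One-command orchestration: assemble -> topology -> controllers ->
robustness -> phenotype, with a config mapping and a single JSON report.

Unless ``whole_network`` is set, every analysis stage runs on the main
(largest weakly connected) component. Every stochastic stage's seed is
echoed into the report, and a rerun with the same config produces a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np

from . import assembly, controllers, graph_core, phenotype_stats, robustness, synthetic, topology

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``network`` (``{"path": ..., "dialect": ...}``),
    ``assembly`` (an :class:`~spermnet.assembly.AssemblyConfig` mapping)
    or ``simulate`` (:class:`~spermnet.synthetic.BAGeneratorConfig`
    fields) must provide the input network.
    """

    network: Optional[dict] = None
    assembly: Optional[dict] = None
    simulate: Optional[dict] = None
    stages: dict = field(
        default_factory=lambda: {
            "topology": True,
            "controllers": True,
            "robustness": True,
            "phenotype": True,
        }
    )
    hub_sigma: float = 1.0
    bottleneck_k: Optional[int] = None
    attack_fractions: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    attack_replicates: int = 10
    attack_seed: int = 0
    phenotype_seed: int = 0
    phenotype_annotations: Optional[str] = None
    whole_network: bool = False
    output_dir: Optional[str] = None

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items()})
        sources = [s for s in (cfg.network, cfg.assembly, cfg.simulate) if s]
        if len(sources) != 1:
            raise PipelineConfigError(
                "exactly one of 'network', 'assembly' or 'simulate' must be given"
            )
        if isinstance(cfg.attack_fractions, list):
            cfg.attack_fractions = tuple(cfg.attack_fractions)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _load_input(config: PipelineConfig) -> graph_core.DirectedNetwork:
    if config.network:
        return graph_core.read_network(
            config.network["path"], dialect=config.network.get("dialect", "sif")
        )
    if config.assembly:
        return assembly.assemble(assembly.AssemblyConfig(**config.assembly))
    return synthetic.generate_ba(synthetic.BAGeneratorConfig(**config.simulate))


def run_pipeline(
    config: PipelineConfig | Mapping[str, Any],
) -> dict:
    """Run the enabled stages in order and return the report dict.

    When ``output_dir`` is set, the report is written as ``report.json``
    alongside per-stage TSV tables.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_mapping(config)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}
    t0 = time.perf_counter()

    net = _run_stage("input", lambda: _load_input(config))
    decomp = graph_core.connected_components(net)
    report["input"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_components": decomp.n_components,
        "main_component_share_pct": graph_core.main_component_share(net),
    }
    if config.simulate:
        report["input"]["simulate_seed"] = config.simulate.get("seed")
    work = net if config.whole_network else graph_core.main_component(net)
    report["analysed_nodes"] = work.n_nodes
    report["analysed_edges"] = work.n_edges

    metrics = None
    hubs: list[str] = []
    if config.stages.get("topology", True):
        def _topology():
            rep = topology.topology_report(work)
            m = topology.node_metrics(work)
            fits = {}
            for which in ("in", "out", "total"):
                try:
                    fit = topology.fit_power_law(topology.degree_distribution(m, which))
                    fits[which] = {
                        "gamma": fit.gamma,
                        "r": fit.r,
                        "r_squared": fit.r_squared,
                    }
                except topology.InsufficientDataError:
                    fits[which] = None
            try:
                ck = topology.clustering_vs_degree(m)
                fits["clustering_vs_degree"] = {
                    "gamma": ck.gamma,
                    "r": ck.r,
                    "r_squared": ck.r_squared,
                    "degenerate": ck.degenerate,
                }
            except topology.InsufficientDataError:
                fits["clustering_vs_degree"] = None
            return rep, m, fits

        rep, metrics, fits = _run_stage("topology", _topology)
        report["stages"]["topology"] = rep.to_dict()
        report["stages"]["topology"]["power_law"] = fits
        if outdir:
            metrics.to_csv(outdir / "node_metrics.tsv", sep="\t")

    if config.stages.get("controllers", True):
        def _controllers():
            m = metrics if metrics is not None else topology.node_metrics(work)
            crit, hub_list = controllers.identify_hubs(m, sigma_multiplier=config.hub_sigma)
            split = (
                controllers.kde_split(
                    m.loc[hub_list, "clustering"].to_numpy(), metric="clustering"
                )
                if len(hub_list) >= 5
                else None
            )
            bn = controllers.bottleneck_scores(work)
            k = config.bottleneck_k or max(1, len(hub_list))
            top_bn = controllers.top_bottlenecks(
                bn, k, degrees=m["degree"].to_dict()
            )
            backbone = controllers.control_backbone(work, hub_list, top_bn)
            return m, crit, hub_list, split, bn, top_bn, backbone

        m, crit, hubs, split, bn, top_bn, backbone = _run_stage(
            "controllers", _controllers
        )
        metrics = m
        report["stages"]["controllers"] = {
            "hub_threshold": crit.threshold,
            "degree_mean": crit.mean,
            "degree_std": crit.std,
            "n_hubs": len(hubs),
            "hub_fraction_pct": robustness.hub_hit_probability(len(hubs), work.n_nodes),
            "clustering_subpopulations": (split.n_subpopulations if split else None),
            "n_bottlenecks_ranked": len(top_bn),
            "backbone_nodes": backbone.n_nodes,
            "backbone_edges": backbone.n_edges,
        }
        if outdir:
            hub_set, bn_top_set = set(hubs), set(top_bn)
            table = m.copy()
            table["bottleneck_score"] = [bn.scores[n] for n in table.index]
            table["is_hub"] = [n in hub_set for n in table.index]
            table["is_top_bottleneck"] = [n in bn_top_set for n in table.index]
            table.to_csv(outdir / "controllers.tsv", sep="\t")

    if config.stages.get("robustness", True):
        def _robustness():
            curves = {}
            for mode in ("random", "targeted"):
                curves[mode] = robustness.attack(
                    work,
                    mode=mode,
                    fractions=config.attack_fractions,
                    replicates=config.attack_replicates,
                    seed=config.attack_seed,
                )
            return curves

        curves = _run_stage("robustness", _robustness)
        report["stages"]["robustness"] = {
            "seed": config.attack_seed,
            "replicates": config.attack_replicates,
            "fractions": list(map(float, curves["random"].fractions)),
            "S_random_mean": [round(x, 6) for x in curves["random"].mean_S],
            "S_targeted": [round(x, 6) for x in curves["targeted"].mean_S],
        }
        if outdir:
            with open(outdir / "attack_curve.tsv", "w", encoding="utf-8") as fh:
                fh.write("fraction\tS_random_mean\tS_targeted\n")
                for f, sr, st in zip(
                    curves["random"].fractions,
                    curves["random"].mean_S,
                    curves["targeted"].mean_S,
                ):
                    fh.write(f"{f}\t{sr:.6f}\t{st:.6f}\n")

    if config.stages.get("phenotype", True):
        def _phenotype():
            if config.phenotype_annotations:
                annotations = _read_annotations(config.phenotype_annotations)
            else:
                hub_list = hubs or []
                non_hubs = sorted(work.nodes - set(hub_list))
                annotations = synthetic.simulate_phenotypes(
                    hub_list,
                    non_hubs,
                    synthetic.PhenotypeSimConfig(seed=config.phenotype_seed),
                )
            table = phenotype_stats.build_table(annotations, hubs)
            result = (
                phenotype_stats.chi_square(table)
                if (table.counts.sum(axis=0) > 0).all()
                else None
            )
            return table, result

        table, result = _run_stage("phenotype", _phenotype)
        report["stages"]["phenotype"] = {
            "seed": None if config.phenotype_annotations else config.phenotype_seed,
            "counts": {c: table.counts[c].tolist() for c in table.counts.columns},
            "percentages": {
                c: table.percentages[c].tolist() for c in table.percentages.columns
            },
            "chi_square": (
                {
                    "statistic": result.statistic,
                    "df": result.df,
                    "p_value": result.p_value,
                    "min_expected": result.min_expected,
                }
                if result
                else None
            ),
        }

    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    if outdir:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _run_stage(name: str, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return result


def _read_annotations(path: str | Path) -> dict[str, str]:
    """Read a two-column ``node<TAB>category`` annotation table."""
    annotations: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "node":
                continue
            if len(fields) != 2:
                raise PipelineConfigError(f"{path}:{lineno}: expected node<TAB>category")
            annotations[fields[0]] = fields[1]
    return annotations
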