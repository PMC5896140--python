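# spermnet

Tools for building and dissecting directed molecular-interaction
networks — the kind assembled for whole-cell interactomes such as the
human sperm interactome, where curated pathway exports are merged,
molecule synonyms harmonized, and the result enriched with
high-confidence association edges (confidence score > 900).

The package is aimed at systems biologists who want to go from pathway
edge lists to a quantitative account of a network's control structure:

* **Assembly** — union of pathway fragments, alias harmonization,
  strict score-filtered enrichment restricted to existing molecules.
* **Topology** — the standard panel (diameter, characteristic path
  length, shortest-path census, clustering coefficient C_I =
  2n_I/(k_I(k_I−1)), averaged neighbours) with directed path metrics,
  plus power-law fits of the degree distribution P(k) ~ k^(−γ) by
  log–log least squares (reported with r and R²) or discrete maximum
  likelihood.
* **Controllers** — hubs (degree ≥ μ + σ), party/date hub
  subpopulations via kernel density estimation, bottlenecks
  BN(v) = Σ_s p_s(v) from a shortest-path-tree census, and the control
  backbone (hub-neighborhood ∩ bottleneck-neighborhood).
* **Robustness** — random-failure vs degree-targeted attack curves of
  relative main-component size S(f).
* **Phenotype statistics** — knockout-phenotype contingency tables by
  controller class and the uncorrected Pearson chi-square test.
* **Synthetic data** — a directed preferential-attachment generator
  (p_i = k_i/Σ_j k_j), a fragmenter producing realistic pathway/alias/
  enrichment inputs whose assembly must reconstruct the source, and
  phenotype/subpopulation simulators; everything is seeded.

## Worked example

```python
import spermnet as sn

net = sn.generate_ba(sn.BAGeneratorConfig(n_nodes=1000, m=2, seed=42))
rep = sn.topology_report(net)
print(rep.diameter, round(rep.characteristic_path_length, 3),
      f"{rep.shortest_path_count} ({rep.shortest_path_pct}%)")
# 11 3.217 16774 (1.7%)

m = sn.node_metrics(net)
print(sn.fit_power_law(sn.degree_distribution(m, "total")).gamma)
# -1.8481872157642433   (log-log OLS slope; MLE at k_min=2 gives -2.393)

crit, hubs = sn.identify_hubs(m)
print(len(hubs), round(crit.threshold, 2),
      sn.hub_hit_probability(len(hubs), net.n_nodes))
# 53 9.32 5.3    -> 53 hubs above degree 9.32; a random hit is 5.3% likely

bn = sn.bottleneck_scores(net)
top = sn.top_bottlenecks(bn, len(hubs), degrees=m["degree"].to_dict())
backbone = sn.control_backbone(net, hubs, top)
print(backbone)
# DirectedNetwork(n_nodes=611, n_edges=1134)

random_curve = sn.attack(net, "random", fractions=[0.1, 0.2, 0.3],
                         replicates=10, seed=7)
targeted_curve = sn.attack(net, "targeted", fractions=[0.1, 0.2, 0.3])
print([round(x, 3) for x in random_curve.mean_S])   # [0.895, 0.782, 0.654]
print([round(x, 3) for x in targeted_curve.S[0]])   # [0.602, 0.021, 0.007]
```

The attack curves show the signature scale-free asymmetry: after
removing 20% of nodes at random the main component still holds 78% of
the network, while targeting the highest-degree 20% shatters it to 2%.

The same stages are scriptable from the shell:

```sh
spermnet simulate ba --seed 1 --n-nodes 1000 --out sim/
spermnet topology --network sim/network.tsv --dialect tsv
spermnet hubs --network sim/network.tsv --dialect tsv
spermnet run --config pipeline.yaml   # full pipeline, JSON report
```

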