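# Methods

`spermnet` analyses directed molecular-interaction networks of the kind
obtained by merging curated pathway exports and enriching them with
high-confidence association edges — the construction used for
whole-cell interactomes such as the human sperm interactome. This note
documents the models, conventions and numerical choices behind each
stage, and what the synthetic-data generators do and do not emulate.

## Network model

A network is a set of string node identifiers and a set of directed
edges `(source, target, interaction-label)`, each optionally carrying an
integer confidence score in [0, 1000]. Duplicate triples collapse to one
edge; when duplicates disagree on score the maximum is kept (best
evidence wins). Self-loops are legal, flagged, and excluded from
neighborhood computations. Node identifiers are compared case-sensitively;
identifier harmonization is an explicit assembly step, never the parser's
job.

Connectivity is *weak* (direction ignored for component membership): a
union of directed pathways is essentially never strongly connected, and
the main component of such a union is only meaningful weakly. All
analyses run on the main (largest weak) component by default, with a
whole-network override.

## Assembly

Three stages mirror how a pathway-based interactome is built:

1. **Union** of pathway edge lists, duplicates collapsed.
2. **Harmonization** against an alias table mapping synonyms onto
   canonical identifiers. Resolution is a single lookup: canonical IDs
   must be fixed points, and chains or cycles in the table are rejected
   up front rather than resolved transitively — a chained table is
   almost always a curation error. Harmonization is idempotent and can
   only decrease the node count.
3. **Enrichment** with scored association edges kept only when the
   score is *strictly* greater than the threshold (default 900). The
   associations are undirected evidence, so a surviving pair adds both
   directions. Only pairs whose endpoints already exist in the
   harmonized union are admitted: enrichment completes the network
   among its own molecules rather than expanding it. The alternative
   (admitting novel nodes) is deliberate scope we did not take, since
   it changes the node universe mid-pipeline.

## Topology panel

Path metrics use **directed** reachability: diameter is the longest
finite shortest path; characteristic path length (CPL) the mean over
reachable ordered pairs; the shortest-path census reports the count of
reachable ordered pairs and its percentage of N(N−1), to one decimal
(round half-up). Neighborhood metrics use the **undirected** view: the
clustering coefficient is C_I = 2 n_I / (k_I (k_I − 1)) with k_I the
number of distinct neighbors (self excluded) and n_I the links among
them, defined 0 for k_I < 2; "averaged neighbours" is the mean number of
distinct adjacent nodes. This directed/undirected split follows the
convention of the Cytoscape-style analyzers the panel is modelled on:
the quoted clustering formula is inherently undirected, while the path
statistics of a regulatory network only make sense directed. Betweenness
is the standard Brandes accumulation over directed shortest paths,
normalized by (N−1)(N−2).

## Degree-distribution fits

A scale-free network has P(k) ~ k^(−γ). The default estimator is
ordinary least squares of log10(count) on log10(k) over bins with
count ≥ 1 (zero bins are undefined in log space and omitted; no log
binning). γ is the signed slope, reported with the Pearson correlation
r and R² = r². This reproduces the reporting convention of the network
analyzers that print (γ, r, R²) panels, which is why it stays the
default — but it is *biased shallow* on heavy-tailed data, because the
tail degenerates into many count-1 bins that flatten the regression.
On preferential-attachment networks at N = 5000 the OLS slope magnitude
sits near 1.9 even though the true exponent is near 3.

For estimating the exponent itself the package therefore also provides
the discrete maximum-likelihood estimator (Clauset-style approximation,
γ̂ = 1 + n / Σ ln(k_i / (k_min − ½))), accurate for k_min of a few and
above. The generator acceptance check uses MLE at k_min = m for exactly
this reason; the Table-style reports keep OLS. C(k)-versus-k uses the
same OLS machinery on the mean clustering coefficient per degree class
(classes with mean 0 omitted); on preferential-attachment networks this
fit is expected to be poor — C(k) approximately independent of k —
whereas hierarchical networks give C(k) ~ k^(−1).

## Controllers

**Hubs** are nodes with total degree ≥ μ + σ, with σ the *population*
standard deviation (the network is a census, not a sample). Both the
multiplier and the degree flavor are configurable. When all degrees are
equal, σ = 0 makes every node a hub; this is surfaced as a warning
rather than an error.

**Hub subpopulations** ("party" hubs with low clustering coefficient vs
"date" hubs with high clustering) are detected as modes of a Gaussian
kernel density estimate: Silverman bandwidth
h = 0.9·min(sd, IQR/1.34)·n^(−1/5), density on a 512-point grid over
[min − 3h, max + 3h], boundaries at strict local minima of the gridded
density. Kernel and bandwidth are the most common convention and are
configurable. Limitation: Silverman's rule undersmooths sharp-edged
(e.g. uniform) blocks at n ≈ 100, so a genuinely unimodal block can
occasionally show a shallow spurious interior minimum and split; with
100-point uniform party samples this happens in roughly one draw in
seven. No prominence filter is applied — boundaries are exactly the
strict minima, so results are reproducible and assumption-free.

**Bottlenecks** follow the shortest-path-tree census: for every root s,
build the BFS tree T_s over directed edges, and set p_s(v) = 1 iff more
than |V(T_s)|/4 of the tree's paths meet at v; BN(v) = Σ_s p_s(v).
Two conventions had to be fixed where the published formula is silent:

* *"paths meeting at v"* is read as the size of v's subtree (v plus
  descendants): every path to a descendant passes v, and the path
  terminating at v counts. The root is excluded from its own tree,
  since every path trivially meets it and would inflate every BN by N.
* *tree choice*: among equal-distance BFS parents the lexicographically
  smallest is chosen, making the tree — and therefore BN —
  deterministic and testable. The test-suite oracle applies the same
  rule but computes the census by literally walking every root-to-target
  parent chain.

The **control backbone** intersects the hub neighborhood network (hubs
plus first neighbors, induced edges) with the bottleneck neighborhood
network. The bottleneck list defaults to the top-BN nodes with k equal
to the hub count, keeping the two controller sets comparable in size.

## Robustness

The attack experiment removes a growing fraction of nodes — cumulative
within a replicate, so the survivor set is nested and S(f) monotone by
construction — and reports the largest weak component relative to the
intact network. Random mode uses fresh seeded permutations per
replicate; targeted mode removes in descending total-degree order
computed on the intact network (static ordering, the convention of the
foundational attack-tolerance experiments; adaptive recomputation is a
flag). CPL among survivors is optional and, on large networks, is
estimated from a capped number of BFS sources (default 64) because exact
all-pairs CPL at every (fraction, replicate) grid point is quadratic in
N. The hub-hit probability 100·hubs/N quantifies why random failure is
benign: a uniform removal almost never lands on a controller.

## Knockout-phenotype statistics

Studied nodes carry one of four fertility phenotypes (infertile,
hypofertile, fertility affected, unaffected/normal). Unstudied nodes are
excluded before tabulation, never treated as a fifth category — the
published totals only reproduce under that rule. The test is the
uncorrected Pearson chi-square (no Yates correction; at df = 3 the
correction is both unnecessary and inconsistent with the published
p-value); a warning flags expected counts below 5. Percentages round
half-up to one decimal, matching the printed table format.

## Synthetic data

The generator suite defines the study conditions for all tests:

* **Preferential attachment**: seed clique of m0 = m+1 nodes, complete
  and symmetric (avoids zero-degree attachment pathologies of an empty
  start); each arriving node draws m distinct targets with probability
  k_i/Σk_j on total degree, edges directed new → target, targets drawn
  sequentially with rejection of repeats (exact for m ≪ N). Defaults
  m = 2 at N in the low thousands give γ ≈ 2.4 (MLE) and an
  ultra-small-world CPL.
* **Fragmentation**: every edge is assigned to one of P = 32 pathways
  (the scale of a curated pathway collection), each pathway topped up
  with random extra edges to a coverage fraction (default 5% of edges)
  so fragments overlap; 10% of nodes get a synonym (suffix `.syn`) used
  in a random half of their fragments; the enrichment table samples
  existing edges with scores, a configured share above 900 (default 0,
  under which assembly must reconstruct the source exactly — the
  module's central guarantee).
* **Phenotypes**: per-class multinomials over the four categories with
  class-specific study coverage (35.6% of hubs, 19.6% of non-hubs
  annotated). The non-hub probability vector sums to 0.999 as printed
  and is renormalized.
* **Planted hub metrics**: party values uniform on [0, 0.17], date on
  [0.83, 0.89], with ground-truth labels returned for recovery checks.

What the generators do **not** emulate: degree-degree correlations,
pathway-level modularity, realistic interaction-type vocabularies,
database-snapshot noise in alias tables, or any biological identity of
nodes. Tests passing on this synthetic product show the algorithms are
correct and the pipeline reconstructs its input under the stated
conditions; they do not validate biological conclusions on real
interactomes.

## Problem sizes

Property suites run on 500 random digraphs (N ≤ 30 for path metrics,
N ≤ 8 for the bottleneck census) against brute-force oracles; exponent
recovery uses 10 networks at N = 5000, attack asymmetry one network at
N = 2000 with 20 random replicates over removal fractions 0.01–0.30.
These sizes make the stochastic checks stable while keeping the whole
suite fast.

## Known limitations

* OLS exponents from raw histograms are biased shallow (see above);
  compare with the MLE before interpreting γ.
* BN scores are O(N·(N+E)); on networks beyond ~10^4 nodes the census
  is the slowest stage.
* The KDE boundary rule has no prominence threshold; see the
  subpopulation caveat above.
* SIF/TSV edge lists cannot represent isolated nodes; writing drops
  them with a warning (GraphML export preserves them).
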