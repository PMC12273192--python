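# rxnnet

Reaction knowledge graphs from atom-mapped reaction SMILES: cleaning,
bipartite network construction, and the statistical toolbox used to ask
whether a corpus of organic chemistry behaves like a scale-free,
hierarchical, core–periphery network.

## Who this is for

Synthesis-informatics groups sit on large collections of reactions —
electronic lab notebooks, patent extractions, commercial databases — and
want to compare their *knowledge structure*: how densely molecules are
reused, whether a few building-block hubs dominate, whether a recycled
"core" of chemistry exists, and how molecular complexity varies across the
network. `rxnnet` implements that entire analysis on any file of
atom-mapped reaction SMILES (`reactants>agents>products`, one reaction per
line), and ships a synthetic corpus generator so every stage is testable
without proprietary data.

## What it computes

**ETL.** Components sharing an atom-map number with the product are
reactants; all others are reagents. Reactants and products are neutralized
(hydrogen-adjustable charges cancelled), then records are kept only if
they are single-step, have exactly one product, at least one reactant, a
product different from every reactant, and no dummy atoms. Reactions
differing only in reagents collapse onto one reaction key.

**Graphs.** A directed bipartite graph (molecule and reaction nodes;
reactant and product edges) plus two monopartite projections: the molecule
graph (reactant→product, parallel edges collapsed with multiplicities) and
the reaction graph (reactions sharing a molecule).

**Scale-free statistics.** Degree tails are fitted to the discrete power
law P(k) = k^(−γ) / ζ(γ, k_min) by maximum likelihood, with k_min chosen
by minimizing the Kolmogorov–Smirnov distance between empirical and fitted
tail CCDFs. Five alternative tail families (truncated power law,
log-normal, positive log-normal, exponential, stretched exponential) are
fitted by discretized MLE and compared with Vuong normalized
likelihood-ratio tests.

**Hierarchy and components.** Hub molecules (degree > 100 × average),
shortest-path distributions (exact or source-sampled BFS), degree-dependent
betweenness (exact or pivot-sampled Brandes) and clustering c̄(k),
core/periphery/island decomposition from the SCC and CC spectra, and
molecular descriptors (MW, heavy atoms, rings, chiral atoms, Fsp3, QED)
summarized per structural class.

## Worked example

```bash
rxnnet run --n-reactions 400 --seed 5 --out out/
```

generates a 400-reaction synthetic corpus, cleans it, builds the graphs
and writes one JSON per report table. `out/table_1.json`:

```json
{
  "avg_total_degree": 2.8,
  "edge_to_node_ratio": 1.4,
  "n_edges_total": 1085,
  "n_molecule_nodes": 416,
  "n_nodes_total": 775,
  "n_product_edges": 359,
  "n_reactant_edges": 726,
  "n_reaction_nodes": 359
}
```

Product edges always equal reaction nodes (each clean reaction forms one
product; 400 generated records deduplicate to 359 distinct reactions), and
the edge-to-node ratio 1.40 says each node participates in roughly 1.4
links — the corpus-connectivity number used to compare sources.
`out/table_2.json` holds the tail fits; on this corpus the out-degree tail
fits γ ≈ 2.56 at k_min = 1 (heavy-tailed molecule reuse), while
`out/table_5.json` reports `core_exists: false` with ~98% of nodes in the
periphery — the expected regime for a corpus without directed reaction
cycles.

Python API equivalents live in `rxnnet.synthetic`, `rxnnet.etl`,
`rxnnet.graphs`, `rxnnet.powerfit`, `rxnnet.topology`,
`rxnnet.components`, `rxnnet.descriptors` and `rxnnet.pipeline`.

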