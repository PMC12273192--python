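# Methods

## The network model

A cleaned reaction corpus is represented as a directed bipartite graph
with molecule nodes (identified by canonical SMILES, atom maps dropped,
stereochemistry kept) and reaction nodes (identified by the reagent-blind
key: sorted canonical reactants `>>` canonical product). Every clean
reaction contributes one reactant edge per distinct reactant and exactly
one product edge, so reaction out-degree is identically one and the
product-edge count equals the reaction-node count on every corpus — a
useful built-in consistency check. Reagents never enter the graph: a
reaction is defined by what contributes atoms to the product, and records
differing only in conditions collapse onto one node.

Two monopartite views are projected from the bipartite graph. The
molecule graph links each reactant to its product (directed); parallel
edges from different reactions are collapsed and the count kept as an edge
multiplicity, because degree-based statistics (hub thresholds, average
degrees) are about distinct chemical neighbours, not repetition counts.
The reaction graph links two reactions sharing any molecule; a molecule
incident to *d* reactions induces a *d*-clique, so materialization is
guarded by an optional per-molecule degree cap for hub-dominated corpora.

## Cleaning rules

Role assignment is purely syntactic: a left-slot or above-arrow component
is a reactant iff it shares at least one atom-map number with the product.
Reactants and products then pass through the RDKit uncharger, which
cancels every formal charge fixable by adding or removing hydrogens
(quaternary ammonium survives); neutralization precedes the filters so a
charged and a neutral form of the same molecule collapse to one node.
Records are rejected (with a recorded reason) if they are multi-arrow
strings, have more or fewer than one product component, no reactant after
role assignment, a product canonically equal to any reactant, a dummy
atom in any component, or — when a minimum-yield threshold is configured,
for sources curated that way — a recorded yield below it. Reagents are
not neutralized: the cleaning contract names only reactants and products,
and reagents take no further part in the analysis.

## Heavy-tail fitting

Degree samples are fitted to the discrete (zeta) power law
P(k) = k^(−γ)/ζ(γ, k_min) by maximizing the exact discrete log-likelihood
with bounded scalar optimization of γ ∈ (1, 20] (tolerance 1e-6). The
tail start k_min is selected by scanning candidates (default [1, 100]
intersected with the support, requiring ≥ 10 tail points and ≥ 2 distinct
values) and minimizing the Kolmogorov–Smirnov distance between the
empirical and fitted tail CCDFs; ties break toward the smaller k_min,
i.e. the larger tail.

Alternative families are fitted at the same k_min by discretized MLE:
a continuous density is given the mass it places on unit intervals
centred at integers, P(k) = F(k+½) − F(k−½), renormalized over
k ≥ k_min. The discrete exponential reduces to a geometric law with a
closed-form MLE; log-normal (and its μ ≥ 0 "positive" variant) and
stretched-exponential (Weibull) parameters are found by L-BFGS-B from
three seeded starts to guard against local optima. The truncated power
law is defined directly on the integers, P(k) ∝ k^(−γ) e^(−λk), with its
normalizing constant computed by direct summation; λ is bounded below at
3e-5 so the summation horizon stays finite, which is unrestrictive for
degree samples whose support ends far earlier.

Fitted families are compared with the Vuong normalized likelihood-ratio
statistic R = (L_a − L_b)/(σ√n), σ being the standard deviation of
per-observation log-likelihood differences, with a two-sided normal
p-value; |R| below the 5% critical value is reported as inconclusive.
On exact power-law samples this machinery reproduces the expected
qualitative pattern: exponential and stretched-exponential are rejected
essentially always, while log-normal frequently remains inconclusive —
the generic situation for real heavy-tailed networks.

One caveat discovered while validating: the popular closed-form
continuous approximation γ̂ ≈ 1 + n/Σ ln(k_i/(k_min−½)) deviates from the
discrete MLE by ~0.13 at k_min = 2 (γ = 2.5) and is trusted as a
cross-check only for k_min ≳ 6, where the deviation falls to ~0.01.

## Hierarchy measures

Hubs are molecules whose total degree on the collapsed molecule graph
exceeds 100 × the average degree (2|E|/|V|); an in-degree ranking with
the analogous cut is provided separately, since the most-formed products
and the most-used reactants answer different questions. Shortest-path
distributions use unit-weight BFS (scipy.sparse.csgraph) over the
undirected skeleton by default, with a directed option; graphs up to 1e4
nodes are done exactly, larger ones from sampled sources. Betweenness
uses Brandes' algorithm (igraph), exact up to 5e3 nodes and otherwise
estimated from random pivot sources rescaled by n/n_pivots; with 1500
pivots on a ~2000-node graph the top-decile mean relative error is ~6%.
Global clustering (transitivity) carries a node-deletion jackknife
standard error computed in closed form from per-node triangle and triple
counts. Degree-dependent profiles c̄(k) and betweenness-by-degree use
exact integer bins up to degree 64 and ×1.5 logarithmic bins above, with
least-squares log–log slopes over bins with positive means.

## Component decomposition

Strongly connected components are computed on the directed bipartite
graph, connected components on its undirected skeleton. The central
component is the largest CC (a warning is logged if it fails to dominate
the runner-up 10-fold, but it is still taken as central — a corpus
without a dominant CC retains a meaningful main component). The core is
the largest SCC, recognised only when it has ≥ 10 nodes and is ≥ 10× the
second-largest SCC; both constants are configuration. There is no
canonical rule for "significantly larger" — this declared convention
admits tiny-but-real cores (a few hundred nodes in a multi-million-node
patent corpus) while rejecting the flat SCC spectra of cycle-free
corpora. The core is verified to lie inside the central component (it is
demoted with a warning otherwise); periphery is the central component
minus the core; islands are everything else. Molecule-level labels are
inherited from the bipartite labels.

## Descriptors

Six per-molecule descriptors: molecular weight, heavy atoms, SSSR ring
count, specified tetrahedral stereocentres (potential-but-unassigned
centres are not counted — the stricter, reproducible reading), Fsp3
(undefined and reported missing for carbon-free species) and QED in its
mean-weighted-desirability form. Class summaries (core / periphery /
island, plus the overlapping hub class) report uncropped means and
standard deviations; the ±2 SD cropping applies only to the distribution
views intended for plotting.

## The synthetic generator

The generator emulates the statistical structure of real reaction corpora
without any chemical realism: products are syntactically valid bonded
concatenations of their reactants' atoms, with map numbers copied from the
reactants (a lone reactant gets one extra unmapped carbon so the product
is never a no-op). Its defaults are the study conditions used throughout
the tests:

* **Reuse** (`reuse_prob` = 0.9, `attach_strength` = 1): each reactant
  slot draws an existing molecule with probability ∝ use-count + 1, via a
  ball-list (one entry per past use, plus a uniform component). This
  yields the heavy-tailed reuse distribution — maximum out-degree orders
  of magnitude above the median — that the tail fitting assumes.
* **Triadic closure** (`closure_prob` = 0.08): a slot after the first is,
  with this probability, filled from the first reactant's current reaction
  neighborhood. Without it the molecule graphs have flat, near-zero
  degree-dependent clustering; with it, triangles accrue at hubs in
  proportion to their degree, giving the hierarchical c̄(k) ≈ k^(−1)
  decay (measured slope ≈ −0.9 at 20k reactions). The value was chosen so
  that decay appears while hub formation at the 100 × d_avg threshold
  survives; larger values (≥ 0.1) dilute preferential attachment enough
  to suppress hubs at that cut.
* **Reactant counts** (1/2/3 with weights 0.2/0.6/0.2): bimolecular
  reactions dominate real corpora.
* **Cycles** (`cycle_prob`, default 0): probability the product is an
  existing molecule, the mechanism by which a strongly connected core can
  emerge. A planted-cycle option appends an exact directed reaction cycle
  (molecule_i + hub → molecule_{i+1}) of known size for ground-truth core
  recovery.
* **Dirt**: each violation kind is injected as an independent Bernoulli
  per line — extra product component, map-stripped product (no reactant
  survives role assignment), product copied from a reactant, dummy atom
  bonded into the product, a deprotonatable/protonatable charge on a
  reactant (repaired, not rejected), or a duplicate of the previous clean
  line with different reagents (collapsed, not rejected).
* **Metadata**: yields uniform on [5, 100]%, Poisson(0.8) unmapped
  reagents from a small solvent vocabulary, a fixed required seed.

Building blocks are linear C/O/N chains enumerated so that ~3^k distinct
blocks exist below k extra heavy atoms, keeping molecule sizes slowly
growing; product size is capped (default 120 heavy atoms) by letting
oversized co-reactants contribute no atoms, which bounds molecular growth
over long runs at the cost of occasionally demoting a reactant to reagent
downstream. A separate designed corpus (`generate_trend_dataset`) places
a tiny universal hub, a planted cycle of mid-weight isomers, hub-attached
periphery reactions on mid-size blocks, and disconnected three-block
island reactions on large blocks, so that mean molecular weight rises
monotonically hub → core → periphery → island — the gradient the
descriptor summaries are built to resolve.

What the generator does **not** emulate: valid chemistry (no valence-aware
transformations beyond syntactic bonding), realistic reagent roles,
reaction classes, or temporal structure. Tests passing on synthetic
corpora therefore validate the *graph-statistical* machinery — cleaning
semantics, network construction, estimators, decompositions — not any
chemical claim about real corpora.

## Sizes, seeds and numerical conventions

The standard test corpus uses 20,000 reactions (network statistics
stabilize there while the full SMILES round-trip stays fast); oracle
comparisons use ~2,000–5,000-node graphs where exact algorithms are
cheap; estimator-recovery checks use 1e5-point samples where the MLE's
standard error (≈ (γ−1)/√n) is well below the tolerances being checked.
The discrete power-law sampler inverts a cumulative table truncated where
the remaining mass drops below 1e-9 (capped at 2e6 entries) and resolves
rarer draws exactly by bisection on the Hurwitz-zeta CCDF, so it is exact
over the full support. All randomness flows through numpy Generators
seeded from explicit configuration; identical configurations reproduce
byte-identical corpora and reports.

## Known limitations

* Molecule identity is canonical SMILES with stereo retained; corpora
  mixing mapped/unmapped stereo annotations of the same species will keep
  them distinct.
* The reaction-graph projection is quadratic around hubs; use the degree
  cap on hub-dominated corpora.
* The truncated-power-law rate is bounded below (3e-5), so
  indistinguishably-near-pure power laws report the boundary rate.
* Exact betweenness beyond ~5e3 nodes and exact all-pairs paths beyond
  1e4 nodes are deliberately out of scope; the sampled estimators carry
  their seeds in the reports.
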